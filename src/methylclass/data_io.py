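"""Tabular input/output for methylome classification.

Three delimited-text inputs drive the pipeline:

* a probes x samples matrix of beta values (methylation fractions in [0, 1]),
  with probe IDs in the first column and sample IDs in the header;
* a two-column sample -> subtype label table;
* a probe annotation manifest in the style of the Illumina
  HumanMethylation450 (GPL13534) manifest, mapping probe IDs to gene symbols.

Delimiters are auto-detected among tab and comma (ties go to tab, the
GEO-style convention). Probe and sample IDs are matched case-sensitively.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigError, ParseError, ValidationError

logger = logging.getLogger(__name__)

#: absolute tolerance when checking beta values against the [0, 1] range
BETA_RANGE_TOL = 1e-9


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class MethylationMatrix:
    """Dense beta-value matrix, rows = probes, columns = samples.

    Beta values are dimensionless methylated-signal fractions in [0, 1].
    """

    probe_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.probe_ids = [str(p) for p in self.probe_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        validate_beta_matrix(self)

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def probe_index(self, probe_ids: Sequence[str]) -> np.ndarray:
        """Row indices of the given probes, erroring on any absentee."""
        lookup = {p: i for i, p in enumerate(self.probe_ids)}
        missing = [p for p in probe_ids if p not in lookup]
        if missing:
            raise ValidationError(
                f"{len(missing)} probe(s) absent from matrix: {missing[:5]}"
            )
        return np.array([lookup[p] for p in probe_ids], dtype=int)

    def subset_probes(self, probe_ids: Sequence[str]) -> "MethylationMatrix":
        idx = self.probe_index(probe_ids)
        return MethylationMatrix(
            probe_ids=[self.probe_ids[i] for i in idx],
            sample_ids=list(self.sample_ids),
            values=self.values[idx, :],
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "MethylationMatrix":
        lookup = {s: j for j, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in lookup]
        if missing:
            raise ValidationError(
                f"{len(missing)} sample(s) absent from matrix: {missing[:5]}"
            )
        idx = np.array([lookup[s] for s in sample_ids], dtype=int)
        return MethylationMatrix(
            probe_ids=list(self.probe_ids),
            sample_ids=[self.sample_ids[j] for j in idx],
            values=self.values[:, idx],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.probe_ids, columns=self.sample_ids
        )


@dataclass
class LabelSet:
    """Sample -> subtype assignment with a sorted category vocabulary."""

    assignments: dict[str, str]
    categories: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        observed = sorted(set(self.assignments.values()))
        if not self.categories:
            self.categories = observed
        elif sorted(set(self.categories)) != observed or len(
            set(self.categories)
        ) != len(self.categories):
            raise ValidationError(
                "categories must be exactly the distinct assigned labels"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.assignments)

    def class_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in self.categories}
        for lab in self.assignments.values():
            counts[lab] += 1
        return counts

    def y(self, sample_ids: Sequence[str]) -> np.ndarray:
        """Integer class codes (indices into ``categories``) for the samples."""
        code = {c: i for i, c in enumerate(self.categories)}
        try:
            return np.array([code[self.assignments[s]] for s in sample_ids])
        except KeyError as exc:  # pragma: no cover - defensive
            raise ValidationError(f"sample without label: {exc}") from exc

    def restrict(self, sample_ids: Iterable[str]) -> "LabelSet":
        keep = {s: self.assignments[s] for s in sample_ids}
        return LabelSet(assignments=keep)


class ProbeAnnotation(Mapping[str, frozenset]):
    """Probe -> set-of-gene-symbols map; unannotated probes yield empty sets."""

    def __init__(self, mapping: Mapping[str, Iterable[str]]):
        self._map: dict[str, frozenset] = {}
        for probe, genes in mapping.items():
            gs = frozenset(str(g) for g in genes if str(g))
            if any(not g for g in gs):
                raise ValidationError(f"empty gene symbol for probe {probe!r}")
            self._map[str(probe)] = gs

    def genes_for(self, probe_id: str) -> frozenset:
        return self._map.get(probe_id, frozenset())

    def gene_universe(self) -> set[str]:
        out: set[str] = set()
        for gs in self._map.values():
            out |= gs
        return out

    # Mapping protocol -----------------------------------------------------
    def __getitem__(self, probe_id: str) -> frozenset:
        return self.genes_for(probe_id)

    def __iter__(self):
        return iter(self._map)

    def __len__(self) -> int:
        return len(self._map)

    def __contains__(self, probe_id) -> bool:
        return probe_id in self._map


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_beta_matrix(matrix: MethylationMatrix) -> None:
    values = matrix.values
    if values.ndim != 2:
        raise ValidationError(f"beta matrix must be 2-D, got ndim={values.ndim}")
    n_probes, n_samples = values.shape
    if len(matrix.probe_ids) != n_probes:
        raise ValidationError(
            f"{len(matrix.probe_ids)} probe IDs for {n_probes} rows"
        )
    if len(matrix.sample_ids) != n_samples:
        raise ValidationError(
            f"{len(matrix.sample_ids)} sample IDs for {n_samples} columns"
        )
    for kind, ids in (("probe", matrix.probe_ids), ("sample", matrix.sample_ids)):
        if len(set(ids)) != len(ids):
            counts = Counter(ids)
            dups = sorted(i for i, c in counts.items() if c > 1)
            raise ValidationError(f"duplicate {kind} IDs: {dups[:5]}")
    if not np.isfinite(values).all():
        r, c = np.argwhere(~np.isfinite(values))[0]
        raise ValidationError(
            f"non-finite beta value at probe {matrix.probe_ids[r]!r}, "
            f"sample {matrix.sample_ids[c]!r}"
        )
    bad = (values < -BETA_RANGE_TOL) | (values > 1.0 + BETA_RANGE_TOL)
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValidationError(
            f"beta value {values[r, c]!r} outside [0, 1] at probe "
            f"{matrix.probe_ids[r]!r}, sample {matrix.sample_ids[c]!r}"
        )
    # values within tolerance of the range are snapped onto it
    np.clip(values, 0.0, 1.0, out=values)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _sniff_delimiter(path: Path) -> str:
    """Pick tab or comma from the header line; ties resolve to tab."""
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def read_beta_matrix(
    path: str | Path,
    dialect: str = "probes-as-rows",
    impute_missing: bool = False,
) -> MethylationMatrix:
    """Read a delimited beta-value matrix into probes-as-rows orientation.

    Parameters
    ----------
    dialect
        ``"probes-as-rows"`` (default) or ``"samples-as-rows"``; the latter is
        transposed on read so the in-memory orientation is always probes x
        samples.
    impute_missing
        When True, missing cells are filled with the per-probe median;
        otherwise any missing value is a hard error.
    """
    path = Path(path)
    if dialect not in ("probes-as-rows", "samples-as-rows"):
        raise ConfigError(
            f"dialect must be 'probes-as-rows' or 'samples-as-rows', got {dialect!r}"
        )
    sep = _sniff_delimiter(path)
    frame = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    numeric = frame.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & frame.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ParseError(
            f"malformed numeric cell {frame.iat[r, c]!r} at row "
            f"{frame.index[r]!r}, column {frame.columns[c]!r} of {path}"
        )
    if dialect == "samples-as-rows":
        numeric = numeric.T
    if numeric.isna().to_numpy().any():
        if impute_missing:
            med = numeric.median(axis=1)
            numeric = numeric.apply(lambda col: col.fillna(med))
            logger.info("imputed missing betas with per-probe medians")
        else:
            r, c = np.argwhere(numeric.isna().to_numpy())[0]
            raise ValidationError(
                f"missing beta value at probe {numeric.index[r]!r}, sample "
                f"{numeric.columns[c]!r} (pass impute_missing=True to fill)"
            )
    return MethylationMatrix(
        probe_ids=list(numeric.index.astype(str)),
        sample_ids=list(numeric.columns.astype(str)),
        values=numeric.to_numpy(dtype=float),
    )


def write_beta_matrix(matrix: MethylationMatrix, path: str | Path, sep: str = "\t") -> None:
    """Write a matrix in the probes-as-rows layout with full float precision."""
    frame = matrix.to_frame()
    frame.index.name = "probe_id"
    frame.to_csv(path, sep=sep, float_format="%.17g")


def read_labels(path: str | Path) -> LabelSet:
    """Read a two-column (sample_id, category) table.

    Duplicate identical rows collapse silently; conflicting duplicates are a
    validation error.
    """
    path = Path(path)
    sep = _sniff_delimiter(path)
    frame = pd.read_csv(path, sep=sep, dtype=str)
    if frame.shape[1] < 2:
        raise ParseError(f"label file {path} needs two columns, got {frame.shape[1]}")
    assignments: dict[str, str] = {}
    for sample, label in zip(frame.iloc[:, 0], frame.iloc[:, 1]):
        sample, label = str(sample), str(label)
        if sample in assignments and assignments[sample] != label:
            raise ValidationError(
                f"sample {sample!r} listed with conflicting categories "
                f"{assignments[sample]!r} and {label!r}"
            )
        assignments[sample] = label
    return LabelSet(assignments=assignments)


def write_labels(labels: LabelSet, path: str | Path, sep: str = "\t") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"sample_id{sep}category\n")
        for sample, cat in labels.assignments.items():
            fh.write(f"{sample}{sep}{cat}\n")


def read_annotation(
    path: str | Path,
    probe_column: str = "ID",
    gene_column: str = "UCSC_RefGene_Name",
) -> ProbeAnnotation:
    """Read a GPL13534-style manifest into a probe -> gene-set map.

    Multi-gene cells are split on ``;`` and deduplicated; probes with an
    empty gene cell map to the empty set.
    """
    path = Path(path)
    sep = _sniff_delimiter(path)
    frame = pd.read_csv(path, sep=sep, dtype=str)
    for col in (probe_column, gene_column):
        if col not in frame.columns:
            raise ParseError(
                f"annotation {path} lacks column {col!r}; has {list(frame.columns)}"
            )
    mapping: dict[str, set[str]] = {}
    for probe, cell in zip(frame[probe_column], frame[gene_column]):
        genes = mapping.setdefault(str(probe), set())
        if isinstance(cell, str) and cell.strip():
            genes.update(g.strip() for g in cell.split(";") if g.strip())
    return ProbeAnnotation(mapping)


def map_probes_to_genes(
    probes: Sequence[str], annotation: ProbeAnnotation
) -> set[str]:
    """Union of gene symbols over the probes; unannotated probes add nothing."""
    genes: set[str] = set()
    for probe in probes:
        genes |= annotation.genes_for(probe)
    return genes


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    """One gene per line, lexicographic, the deterministic serialized order."""
    with open(path, "w", encoding="utf-8") as fh:
        for gene in sorted(set(genes)):
            fh.write(f"{gene}\n")


def write_probe_list(probes: Iterable[str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for probe in probes:
            fh.write(f"{probe}\n")
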