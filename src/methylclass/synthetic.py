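"""Synthetic labeled methylome cohorts with known informative probes.

The generator emulates the structure of a multi-subtype tumor methylation
study: a heavily imbalanced seven-class cohort measured on a few thousand
CpG probes, where each subtype carries a small, class-exclusive set of
differentially methylated probes. Background probes draw beta values i.i.d.
from Beta(a, b); an informative probe for class ``c`` draws, for samples of
``c`` only, from a Beta whose mean is shifted by +/- ``effect_delta`` at
fixed concentration ``a + b`` (so the variance scale is preserved), and from
the background for everyone else.

Two presets mirror the training (347 samples) and independent-test (324
samples) cohorts of a seven-subtype glioblastoma study; both share the same
truth probes so a classifier selected on the training preset can be scored
on the test preset.

Real-data features deliberately NOT simulated: probe-probe correlation,
batch effects, bimodal beta distributions of fully (un)methylated CpGs,
copy-number-driven artifacts, cross-hybridizing probes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .data_io import (
    LabelSet,
    MethylationMatrix,
    ProbeAnnotation,
    write_beta_matrix,
    write_labels,
)
from .exceptions import ConfigError

#: training-cohort subtype sizes (total 347)
TRAINING_CLASS_SIZES = {
    "G34": 41,
    "MES": 56,
    "MID": 14,
    "MYCN": 16,
    "RTK": 64,
    "RTK II": 143,
    "RTK III": 13,
}

#: independent-test-cohort subtype sizes (total 324)
TEST_CLASS_SIZES = {
    "G34": 13,
    "MES": 104,
    "MID": 19,
    "MYCN": 17,
    "RTK": 44,
    "RTK II": 118,
    "RTK III": 9,
}

#: probe count of the full-scale methylation array study
FULL_SCALE_N_PROBES = 42_383

#: desk-scale probe count used throughout tests and examples
DESK_N_PROBES = 2_000


@dataclass
class SimulationDesign:
    """Parameters of one synthetic cohort.

    ``background_shape`` (a, b) sets the Beta distribution of uninformative
    probes; ``effect_delta`` is the shift in mean beta of an informative
    probe within its class; ``direction_mix`` is the fraction of informative
    probes that are hypermethylated (the rest are hypomethylated).
    """

    class_sizes: dict[str, int]
    n_probes: int = DESK_N_PROBES
    n_informative_per_class: int = 10
    background_shape: tuple[float, float] = (2.0, 2.0)
    effect_delta: float = 0.3
    direction_mix: float = 0.5
    seed: int = 0
    sample_prefix: str = "S"

    def __post_init__(self) -> None:
        if not self.class_sizes or any(c < 1 for c in self.class_sizes.values()):
            raise ConfigError("every class needs a count of at least 1")
        if sum(self.class_sizes.values()) < 2:
            raise ConfigError("total sample count must be at least 2")
        if self.n_probes < 1:
            raise ConfigError("n_probes must be positive")
        if self.n_informative_per_class < 0:
            raise ConfigError("n_informative_per_class must be non-negative")
        if self.n_informative_per_class * len(self.class_sizes) > self.n_probes:
            raise ConfigError(
                "informative probes exceed n_probes: "
                f"{self.n_informative_per_class} x {len(self.class_sizes)} > "
                f"{self.n_probes}"
            )
        a, b = self.background_shape
        if a <= 0 or b <= 0:
            raise ConfigError("background_shape values must be positive")
        if not (0.0 <= self.effect_delta <= 0.5):
            raise ConfigError("effect_delta must lie in [0, 0.5]")
        if not (0.0 <= self.direction_mix <= 1.0):
            raise ConfigError("direction_mix must lie in [0, 1]")

    @property
    def categories(self) -> list[str]:
        return sorted(self.class_sizes)

    @property
    def n_samples(self) -> int:
        return sum(self.class_sizes.values())


@dataclass
class SyntheticCohort:
    """A generated cohort plus its ground truth of informative probes."""

    matrix: MethylationMatrix
    labels: LabelSet
    truth: dict[str, set[str]] = field(default_factory=dict)

    def truth_probes(self) -> set[str]:
        out: set[str] = set()
        for probes in self.truth.values():
            out |= probes
        return out


def default_training_design(
    n_probes: int = DESK_N_PROBES, **overrides
) -> SimulationDesign:
    """Design mirroring the 347-sample, seven-subtype training cohort.

    ``n_probes`` defaults to the desk scale (2,000); pass
    ``FULL_SCALE_N_PROBES`` (42,383) for the full array scale.
    """
    return SimulationDesign(
        class_sizes=dict(TRAINING_CLASS_SIZES), n_probes=n_probes, **overrides
    )


def default_test_design(
    n_probes: int = DESK_N_PROBES, **overrides
) -> SimulationDesign:
    """Design mirroring the 324-sample independent test cohort.

    Shares probe identities (hence truth probes) with the training design
    whenever n_probes and n_informative_per_class match.
    """
    overrides.setdefault("sample_prefix", "T")
    return SimulationDesign(
        class_sizes=dict(TEST_CLASS_SIZES), n_probes=n_probes, **overrides
    )


def _probe_ids(n_probes: int) -> list[str]:
    width = max(5, len(str(n_probes)))
    return [f"cg{i:0{width}d}" for i in range(n_probes)]


def _shifted_shape(
    shape: tuple[float, float], delta: float
) -> tuple[float, float]:
    """Move the Beta mean by ``delta`` keeping the concentration a+b fixed."""
    a, b = shape
    conc = a + b
    mean = np.clip(a / conc + delta, 1e-3, 1.0 - 1e-3)
    return (mean * conc, (1.0 - mean) * conc)


def generate_cohort(design: SimulationDesign) -> SyntheticCohort:
    """Draw one cohort; byte-identical for identical (design, seed)."""
    rng = np.random.default_rng(np.random.SeedSequence(design.seed))
    categories = design.categories
    probe_ids = _probe_ids(design.n_probes)

    sample_ids: list[str] = []
    sample_class: list[str] = []
    for cat in categories:
        for k in range(design.class_sizes[cat]):
            sample_ids.append(f"{design.sample_prefix}_{cat.replace(' ', '')}_{k:03d}")
            sample_class.append(cat)
    n = len(sample_ids)

    a, b = design.background_shape
    values = rng.beta(a, b, size=(design.n_probes, n))

    # class-exclusive informative blocks at the head of the probe list
    truth: dict[str, set[str]] = {c: set() for c in categories}
    k_inf = design.n_informative_per_class
    n_hyper = int(round(design.direction_mix * k_inf))
    col_of_class = {
        c: np.array([j for j, sc in enumerate(sample_class) if sc == c])
        for c in categories
    }
    for ci, cat in enumerate(categories):
        rows = np.arange(ci * k_inf, (ci + 1) * k_inf)
        truth[cat] = {probe_ids[r] for r in rows}
        cols = col_of_class[cat]
        for j, r in enumerate(rows):
            delta = design.effect_delta if j < n_hyper else -design.effect_delta
            ia, ib = _shifted_shape(design.background_shape, delta)
            values[r, cols] = rng.beta(ia, ib, size=cols.size)

    np.clip(values, 0.0, 1.0, out=values)
    matrix = MethylationMatrix(
        probe_ids=probe_ids, sample_ids=sample_ids, values=values
    )
    labels = LabelSet(
        assignments=dict(zip(sample_ids, sample_class))
    )
    return SyntheticCohort(matrix=matrix, labels=labels, truth=truth)


def shared_truth_pair(
    train_design: SimulationDesign, test_design: SimulationDesign
) -> tuple[SyntheticCohort, SyntheticCohort]:
    """Generate a train/test cohort pair sharing the same truth probes.

    The designs must agree on n_probes, n_informative_per_class and the
    class vocabulary; the test cohort is drawn with an offset seed so its
    noise is independent of the training cohort's.
    """
    if train_design.n_probes != test_design.n_probes:
        raise ConfigError("train and test designs must share n_probes")
    if train_design.n_informative_per_class != test_design.n_informative_per_class:
        raise ConfigError("train and test designs must share informative counts")
    if train_design.categories != test_design.categories:
        raise ConfigError("train and test designs must share the class set")
    test_design = replace(test_design, seed=test_design.seed + 1_000_003)
    train = generate_cohort(train_design)
    test = generate_cohort(test_design)
    assert {c: train.truth[c] for c in train.truth} == test.truth
    return train, test


# ---------------------------------------------------------------------------
# Synthetic annotation and gene sets (for exercising the enrichment stage)
# ---------------------------------------------------------------------------

def synthetic_annotation(
    probe_ids: list[str],
    genes_per_probe: float = 0.8,
    probes_per_gene: int = 2,
    seed: int = 0,
) -> ProbeAnnotation:
    """A synthetic probe -> gene manifest.

    Roughly ``genes_per_probe`` of probes are annotated; consecutive groups
    of ``probes_per_gene`` annotated probes share a gene, reproducing the
    many-probes-to-one-gene structure of real array manifests.
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, 17)))
    annotated = rng.random(len(probe_ids)) < genes_per_probe
    mapping: dict[str, set[str]] = {}
    gi = 0
    run = 0
    for probe, keep in zip(probe_ids, annotated):
        if not keep:
            mapping[probe] = set()
            continue
        mapping[probe] = {f"GENE{gi:05d}"}
        run += 1
        if run >= probes_per_gene:
            gi, run = gi + 1, 0
    return ProbeAnnotation(mapping)


def synthetic_gene_sets(
    universe: list[str],
    n_terms: int = 50,
    set_size: tuple[int, int] = (10, 40),
    seed: int = 0,
    namespace: str = "BP",
) -> dict[str, tuple[str, set[str]]]:
    """Random term -> gene-set draws from a universe, GMT-shaped in memory."""
    rng = np.random.default_rng(np.random.SeedSequence((seed, 23)))
    universe = sorted(universe)
    sets: dict[str, tuple[str, set[str]]] = {}
    lo, hi = set_size
    for t in range(n_terms):
        size = int(rng.integers(lo, hi + 1))
        size = min(size, len(universe))
        members = set(rng.choice(universe, size=size, replace=False))
        sets[f"{namespace}:{t:04d}"] = (f"synthetic term {t}", members)
    return sets


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> dict[str, Path]:
    """Write matrix/labels/truth as the TSV formats the readers accept."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out / "beta_matrix.tsv",
        "labels": out / "labels.tsv",
        "truth": out / "truth_probes.tsv",
    }
    write_beta_matrix(cohort.matrix, paths["matrix"])
    write_labels(cohort.labels, paths["labels"])
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        for cat in sorted(cohort.truth):
            for probe in sorted(cohort.truth[cat]):
                fh.write(f"{cat}\t{probe}\n")
    return paths
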