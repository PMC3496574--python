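"""Synthetic DMET-format case-control datasets with known ground truth.

Each simulated probe is bi-allelic: two distinct alleles X < Y are drawn per
probe and genotypes live on {X/X, X/Y, Y/Y}.  Null probes share one genotype
distribution between classes — Hardy–Weinberg proportions at an allele
frequency drawn uniformly from [0.05, 0.95], the typical situation for
common ADME markers.  Associated probes differ between classes; the
``separation`` convenience places mass (1+s)/2 on X/X and (1-s)/2 on Y/Y in
one class and mirrors it in the other, so s equals the total-variation
distance between the class distributions and s = 1 gives complete
separation.

Randomness is split per probe from a single global seed, so a probe's calls
do not depend on how many other probes are generated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import ValidationError
from .io import DmetDataset, GenotypeCall, NOCALL, canonicalize_genotype

_DIST_TOL = 1e-9

#: Number of markers on the DMET chip; the default dataset width.
DMET_PROBE_COUNT = 1936


@dataclass(frozen=True)
class ProbeSpec:
    """Ground truth for one simulated probe: the two class distributions."""

    probe_id: str
    dist_class_a: dict[str, float]
    dist_class_b: dict[str, float]

    def __post_init__(self) -> None:
        for name, dist in (("A", self.dist_class_a), ("B", self.dist_class_b)):
            if not dist:
                raise ValidationError(f"{self.probe_id}: empty class-{name} distribution")
            total = sum(dist.values())
            if abs(total - 1.0) > _DIST_TOL:
                raise ValidationError(
                    f"{self.probe_id}: class-{name} distribution sums to {total!r}"
                )
            if any(p < 0 for p in dist.values()):
                raise ValidationError(f"{self.probe_id}: negative probability")

    @property
    def is_associated(self) -> bool:
        symbols = set(self.dist_class_a) | set(self.dist_class_b)
        return any(
            abs(self.dist_class_a.get(s, 0.0) - self.dist_class_b.get(s, 0.0))
            > _DIST_TOL
            for s in symbols
        )


@dataclass(frozen=True)
class SyntheticTruth:
    """Per-probe ground truth plus the generator settings that produced it."""

    probes: dict[str, ProbeSpec]
    seed: int
    nocall_rate: float

    @property
    def associated_ids(self) -> list[str]:
        return [pid for pid, spec in self.probes.items() if spec.is_associated]


def _probe_rng(seed: int, index: int) -> np.random.Generator:
    # per-probe stream: independent of generation order and of other probes
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(index,)))


def _hwe_dist(symbols: Sequence[str], q: float) -> dict[str, float]:
    p = 1.0 - q
    return {symbols[0]: p * p, symbols[1]: 2.0 * p * q, symbols[2]: q * q}


def _separation_pair(
    symbols: Sequence[str], s: float
) -> tuple[dict[str, float], dict[str, float]]:
    if not (0.0 < s <= 1.0):
        raise ValidationError(f"separation must lie in (0, 1], got {s}")
    hom_x, _, hom_y = symbols
    if s == 1.0:
        return {hom_x: 1.0}, {hom_y: 1.0}
    a = {hom_x: (1.0 + s) / 2.0, hom_y: (1.0 - s) / 2.0}
    b = {hom_x: (1.0 - s) / 2.0, hom_y: (1.0 + s) / 2.0}
    return a, b


def _canonical_dist(dist: Mapping[str, float]) -> dict[str, float]:
    out: dict[str, float] = {}
    for sym, prob in dist.items():
        call = canonicalize_genotype(sym)
        if call.is_nocall:
            raise ValidationError("NoCall cannot appear in a genotype distribution")
        out[str(call)] = out.get(str(call), 0.0) + float(prob)
    return out


def generate_dataset(
    m_null: int = DMET_PROBE_COUNT,
    m_assoc: int = 0,
    n_class_a: int = 10,
    n_class_b: int = 10,
    effect: float | tuple[Mapping[str, float], Mapping[str, float]] = 1.0,
    nocall_rate: float = 0.0,
    seed: int = 0,
    class_a: str = "A",
    class_b: str = "B",
) -> tuple[DmetDataset, SyntheticTruth]:
    """Generate a DMET-layout dataset with *m_null* null and *m_assoc*
    associated probes over two classes of *n_class_a* and *n_class_b* samples.

    *effect* is either a separation scalar in (0, 1] (see module docstring)
    or an explicit ``(dist_a, dist_b)`` pair of genotype-symbol distributions
    applied to every associated probe.  Each call is independently replaced
    by NoCall with probability *nocall_rate*.  Identical arguments produce a
    bit-identical dataset.
    """
    m = m_null + m_assoc
    if m < 1:
        raise ValidationError("need at least one probe")
    if min(m_null, m_assoc) < 0:
        raise ValidationError("probe counts must be non-negative")
    if n_class_a < 1 or n_class_b < 1:
        raise ValidationError("both classes need at least one sample")
    if not (0.0 <= nocall_rate < 1.0):
        raise ValidationError(f"nocall_rate must lie in [0, 1), got {nocall_rate}")
    if class_a == class_b:
        raise ValidationError("class names must differ")

    explicit_pair: tuple[dict[str, float], dict[str, float]] | None = None
    if not isinstance(effect, (int, float)):
        da, db = effect
        explicit_pair = (_canonical_dist(da), _canonical_dist(db))
        # construction through ProbeSpec below validates the sums

    width = max(4, len(str(m)))
    probe_ids = [f"Probe_{i + 1:0{width}d}" for i in range(m)]
    n = n_class_a + n_class_b
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    labels = {
        sid: (class_a if i < n_class_a else class_b)
        for i, sid in enumerate(sample_ids)
    }

    assoc_rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(m,)))
    assoc_positions = set(
        int(i) for i in assoc_rng.choice(m, size=m_assoc, replace=False)
    )

    bases = np.array(["A", "C", "G", "T"])
    calls: list[list[GenotypeCall]] = []
    specs: dict[str, ProbeSpec] = {}
    for i, pid in enumerate(probe_ids):
        rng = _probe_rng(seed, i)
        x, y = sorted(rng.choice(bases, size=2, replace=False))
        symbols = (f"{x}/{x}", f"{x}/{y}", f"{y}/{y}")
        if i in assoc_positions:
            if explicit_pair is not None:
                dist_a, dist_b = explicit_pair
            else:
                dist_a, dist_b = _separation_pair(symbols, float(effect))
        else:
            q = float(rng.uniform(0.05, 0.95))
            dist_a = _hwe_dist(symbols, q)
            dist_b = dict(dist_a)
        spec = ProbeSpec(pid, dist_a, dist_b)
        specs[pid] = spec

        row: list[GenotypeCall] = []
        for dist, size in ((dist_a, n_class_a), (dist_b, n_class_b)):
            syms = sorted(dist)
            probs = np.array([dist[s] for s in syms], dtype=float)
            probs = probs / probs.sum()
            draws = rng.choice(len(syms), size=size, p=probs)
            row.extend(canonicalize_genotype(syms[d]) for d in draws)
        if nocall_rate > 0.0:
            mask = rng.random(n) < nocall_rate
            row = [NOCALL if hit else call for call, hit in zip(row, mask)]
        calls.append(row)

    dataset = DmetDataset(probe_ids, sample_ids, calls, labels)
    truth = SyntheticTruth(probes=specs, seed=seed, nocall_rate=nocall_rate)
    return dataset, truth


def scale_series(
    sizes: Sequence[int], probes: int = DMET_PROBE_COUNT, seed: int = 0
) -> list[DmetDataset]:
    """One null dataset per requested total sample count, fixed probe count.

    Each size is split evenly into the two classes; sizes below 2 are
    rejected (both classes need a sample).
    """
    if not sizes:
        raise ValidationError("sizes must be non-empty")
    datasets = []
    for size in sizes:
        if size < 2:
            raise ValidationError(f"sample count must be at least 2, got {size}")
        n_a = size // 2
        dataset, _ = generate_dataset(
            m_null=probes,
            m_assoc=0,
            n_class_a=n_a,
            n_class_b=size - n_a,
            nocall_rate=0.0,
            seed=seed,
        )
        datasets.append(dataset)
    return datasets


def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    """Serialize ground truth as TSV (distributions as JSON strings)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("probe_id\tis_associated\tdist_a\tdist_b\n")
        for pid, spec in truth.probes.items():
            fh.write(
                "\t".join(
                    (
                        pid,
                        str(spec.is_associated),
                        json.dumps(spec.dist_class_a, sort_keys=True),
                        json.dumps(spec.dist_class_b, sort_keys=True),
                    )
                )
                + "\n"
            )
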