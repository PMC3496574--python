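"""Per-probe case-control association testing with Fisher's exact test.

For each probe the genotype distribution of two selected sample classes is
tabulated into a 2×k contingency table (k observed genotype symbols).  In
``per_symbol`` mode each symbol is tested against the pooled rest in a 2×2
Fisher exact test — matching how pharmacogenomic findings are usually
reported ("the homozygous genotype C/C in gene X, P=...").  In ``omnibus``
mode a single exact 2×k conditional test is run per probe.

Two-sided p-values follow the probability method: the sum, over all tables
with the observed margins, of hypergeometric point probabilities less than
or equal to that of the observed table (relative tie tolerance 1e-9).

An optional pre-filter skips the exact test for probes whose maximal
between-class genotype frequency difference does not exceed a threshold.
Bonferroni and Benjamini–Hochberg adjustments are computed over the number
of tests actually performed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.special import gammaln

from .errors import CapacityError, ConfigurationError
from .io import NOCALL, DmetDataset

#: Relative tolerance used to treat near-equal point probabilities as ties.
TIE_RTOL = 1e-9

#: Default cap on the number of tables enumerated by the exact 2×k test.
DEFAULT_MAX_TABLES = 5_000_000


# ---------------------------------------------------------------------------
# options and result containers


@dataclass(frozen=True)
class AnalysisOptions:
    """Configuration of one association run.

    Parameters
    ----------
    class_a, class_b
        The two sample classes to compare (must differ and both be present).
    mode
        ``per_symbol`` — one 2×2 test per observed genotype symbol
        (symbol vs all others); ``omnibus`` — one exact 2×k test per probe.
    correction
        Which adjusted p-value the reporting layer should emphasise; all
        three columns (raw, Bonferroni, BH) are always computed.
    prefilter_threshold
        When not ``None``, only probes whose maximal between-class genotype
        frequency difference exceeds this value are tested; 0 keeps every
        probe showing any difference.  ``None`` disables the pre-filter.
    nocall_policy
        ``exclude`` drops NoCall samples from a probe's table (they are
        non-measurements); ``as_category`` keeps them as their own column.
    """

    class_a: str
    class_b: str
    mode: Literal["per_symbol", "omnibus"] = "per_symbol"
    correction: Literal["none", "bonferroni", "fdr"] = "none"
    prefilter_threshold: float | None = None
    nocall_policy: Literal["exclude", "as_category"] = "exclude"

    def __post_init__(self) -> None:
        if self.class_a == self.class_b:
            raise ConfigurationError("class_a and class_b must differ")
        if self.mode not in ("per_symbol", "omnibus"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        if self.correction not in ("none", "bonferroni", "fdr"):
            raise ConfigurationError(f"unknown correction {self.correction!r}")
        if self.nocall_policy not in ("exclude", "as_category"):
            raise ConfigurationError(f"unknown nocall policy {self.nocall_policy!r}")
        if self.prefilter_threshold is not None and not (
            0.0 <= self.prefilter_threshold <= 1.0
        ):
            raise ConfigurationError("prefilter threshold must lie in [0, 1]")


@dataclass(frozen=True)
class ContingencySet:
    """Per-probe genotype counts by class: rows = the two classes, columns =
    genotype symbols observed at this probe (lexicographic order)."""

    probe_id: str
    categories: tuple[str, ...]
    counts: np.ndarray  # shape (2, k), int
    class_names: tuple[str, str]
    n_excluded_nocall: tuple[int, int] = (0, 0)

    @property
    def row_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1) if self.counts.size else np.zeros(2, int)

    @property
    def degenerate(self) -> bool:
        """True when a class has no measured genotype at this probe."""
        return bool(self.counts.size == 0 or (self.row_sums == 0).any())


@dataclass(frozen=True)
class AssociationResult:
    """One performed (or skipped) test for one probe.

    ``tested_symbol`` is the genotype symbol for per-symbol 2×2 tests or
    ``"omnibus"`` for the full-table test; skipped probes carry
    ``prefiltered=True``, no p-values and a human-readable *reason*.
    """

    probe_id: str
    tested_symbol: str | None
    table: np.ndarray | None
    p_raw: float | None
    p_bonferroni: float | None = None
    p_fdr: float | None = None
    prefiltered: bool = False
    reason: str | None = None


# ---------------------------------------------------------------------------
# contingency tables


def build_contingency(
    dataset: DmetDataset, probe_id: str, options: AnalysisOptions
) -> ContingencySet:
    """Tabulate one probe's genotype symbols by class."""
    for cls in (options.class_a, options.class_b):
        if not dataset.samples_of(cls):
            raise ConfigurationError(f"class {cls!r} has no samples")
    row = dataset.probe_row(probe_id)
    by_sample = dict(zip(dataset.sample_ids, row))

    counters: list[dict[str, int]] = []
    excluded: list[int] = []
    for cls in (options.class_a, options.class_b):
        counts: dict[str, int] = {}
        n_nocall = 0
        for sid in dataset.samples_of(cls):
            call = by_sample[sid]
            if call is NOCALL or call.is_nocall:
                if options.nocall_policy == "exclude":
                    n_nocall += 1
                    continue
                key = "NoCall"
            else:
                key = str(call)
            counts[key] = counts.get(key, 0) + 1
        counters.append(counts)
        excluded.append(n_nocall)

    categories = tuple(sorted(set(counters[0]) | set(counters[1])))
    matrix = np.array(
        [[c.get(cat, 0) for cat in categories] for c in counters], dtype=np.int64
    ).reshape(2, len(categories))
    return ContingencySet(
        probe_id=probe_id,
        categories=categories,
        counts=matrix,
        class_names=(options.class_a, options.class_b),
        n_excluded_nocall=(excluded[0], excluded[1]),
    )


# ---------------------------------------------------------------------------
# exact tests


def _validate_table(table) -> np.ndarray:
    t = np.asarray(table, dtype=np.int64)
    if t.ndim != 2 or t.shape[0] != 2:
        raise ValueError(f"expected a 2×k table, got shape {t.shape}")
    if (t < 0).any():
        raise ValueError("contingency table entries must be non-negative")
    if t.sum() < 1:
        raise ValueError("contingency table must contain at least one count")
    return t


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p-value for a 2×2 table (probability method).

    Enumerates every table with the observed margins and sums the
    hypergeometric point probabilities that do not exceed the observed
    table's probability (relative tie tolerance :data:`TIE_RTOL`).
    """
    t = _validate_table(table)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2×2 table, got shape {t.shape}")
    r0 = int(t[0].sum())
    c0, c1 = int(t[0, 0] + t[1, 0]), int(t[0, 1] + t[1, 1])
    n = r0 + int(t[1].sum())

    a_min = max(0, r0 - c1)
    a_max = min(r0, c0)
    a = np.arange(a_min, a_max + 1)
    logp = (
        _log_binom(c0, a)
        + _log_binom(c1, r0 - a)
        - _log_binom(n, r0)
    )
    p = np.exp(logp)
    p_obs = p[int(t[0, 0]) - a_min]
    return float(min(1.0, p[p <= p_obs * (1.0 + TIE_RTOL)].sum()))


def _log_binom(n, k):
    n = np.asarray(n, dtype=np.float64)
    k = np.asarray(k, dtype=np.float64)
    return gammaln(n + 1.0) - gammaln(k + 1.0) - gammaln(n - k + 1.0)


def fisher_exact_rxc(table, max_tables: int = DEFAULT_MAX_TABLES) -> float:
    """Exact conditional p-value for a 2×k table with fixed margins.

    Enumerates all top-row compositions compatible with the margins
    (multivariate hypergeometric null) and sums point probabilities not
    exceeding the observed one.  Reduces to :func:`fisher_exact_2x2` at
    k = 2 and returns 1.0 at k = 1.

    Raises :class:`CapacityError` when the enumeration would exceed
    *max_tables* tables; per-symbol 2×2 mode has no such limit.
    """
    t = _validate_table(table)
    k = t.shape[1]
    if k == 1:
        return 1.0
    col = t.sum(axis=0).astype(int)
    r0 = int(t[0].sum())
    n = int(t.sum())

    bound = 1
    for c in col:
        bound *= min(int(c), r0) + 1
        if bound > max_tables:
            raise CapacityError(
                f"exact 2×{k} enumeration would exceed {max_tables} tables; "
                "use per_symbol mode for this probe"
            )

    # per-column log-binomial lookup: lb[j][a] = log C(col[j], a)
    lb = [
        _log_binom(int(c), np.arange(int(c) + 1)) for c in col
    ]
    log_denom = float(_log_binom(n, r0))
    suffix_cap = np.concatenate((np.cumsum(col[::-1])[::-1][1:], [0]))

    log_obs = sum(float(lb[j][int(t[0, j])]) for j in range(k)) - log_denom
    threshold = math.exp(log_obs) * (1.0 + TIE_RTOL)

    total = 0.0

    def recurse(j: int, remaining: int, acc: float) -> None:
        nonlocal total
        if j == k - 1:
            if remaining <= int(col[j]):
                p = math.exp(acc + float(lb[j][remaining]) - log_denom)
                if p <= threshold:
                    total += p
            return
        lo = max(0, remaining - int(suffix_cap[j]))
        hi = min(int(col[j]), remaining)
        for a in range(lo, hi + 1):
            recurse(j + 1, remaining - a, acc + float(lb[j][a]))

    recurse(0, r0, 0.0)
    return float(min(1.0, total))


# ---------------------------------------------------------------------------
# pre-filter


def max_frequency_difference(contingency: ContingencySet) -> float:
    """Largest |freq_A − freq_B| over the probe's genotype categories."""
    rows = contingency.row_sums
    if contingency.counts.size == 0 or (rows == 0).any():
        return math.nan
    freqs = contingency.counts / rows[:, None]
    return float(np.abs(freqs[0] - freqs[1]).max())


def prefilter(contingency: ContingencySet, threshold: float) -> bool:
    """True iff the probe should be tested: max between-class genotype
    frequency difference strictly exceeds *threshold*.

    A probe with no measured genotype in one class is untestable and
    returns False.
    """
    diff = max_frequency_difference(contingency)
    if math.isnan(diff):
        return False
    return diff > threshold


# ---------------------------------------------------------------------------
# multiple-testing corrections


def _check_pvalues(p_values: Iterable[float]) -> list[float]:
    ps = [float(p) for p in p_values]
    for p in ps:
        if not (0.0 < p <= 1.0):
            raise ValueError(f"p-values must lie in (0, 1], got {p}")
    return ps


def bonferroni(p_values: Sequence[float], m: int) -> list[float]:
    """Bonferroni adjustment over a universe of *m* tests: min(1, m·p)."""
    ps = _check_pvalues(p_values)
    if m < len(ps):
        raise ValueError(
            f"correction universe m={m} smaller than number of p-values {len(ps)}"
        )
    if m < 1:
        raise ValueError("m must be a positive integer")
    return [min(1.0, m * p) for p in ps]


def fdr_bh(p_values: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    For sorted p(1) ≤ … ≤ p(m): q(i) = min over j ≥ i of min(1, m·p(j)/j).
    """
    ps = np.asarray(_check_pvalues(p_values), dtype=float)
    m = ps.size
    if m == 0:
        return []
    order = np.argsort(ps, kind="stable")
    ranked = ps[order] * m / np.arange(1, m + 1)
    q = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    out = np.empty(m, dtype=float)
    out[order] = q
    return out.tolist()


# ---------------------------------------------------------------------------
# the driver


def analyze(
    dataset: DmetDataset, options: AnalysisOptions
) -> list[AssociationResult]:
    """Run the association workflow over every probe of *dataset*.

    Returns one :class:`AssociationResult` per performed test (per symbol in
    ``per_symbol`` mode, per probe in ``omnibus`` mode) plus one prefiltered
    record per skipped probe.  Adjusted p-values use the number of tests
    actually performed as the correction universe.
    """
    if dataset.n_probes < 1:
        raise ConfigurationError("dataset has no probes to analyse")
    labels = set(dataset.class_labels.values())
    for cls in (options.class_a, options.class_b):
        if cls not in labels:
            raise ConfigurationError(f"class {cls!r} not present in dataset")

    results: list[AssociationResult] = []
    tested_idx: list[int] = []
    for probe_id in dataset.probe_ids:
        cs = build_contingency(dataset, probe_id, options)
        if cs.degenerate:
            results.append(
                AssociationResult(
                    probe_id=probe_id,
                    tested_symbol=None,
                    table=None,
                    p_raw=None,
                    prefiltered=True,
                    reason="untestable: a class has no measured genotype",
                )
            )
            continue
        if options.prefilter_threshold is not None and not prefilter(
            cs, options.prefilter_threshold
        ):
            results.append(
                AssociationResult(
                    probe_id=probe_id,
                    tested_symbol=None,
                    table=None,
                    p_raw=None,
                    prefiltered=True,
                    reason=(
                        "max genotype frequency difference "
                        f"{max_frequency_difference(cs):.4g} ≤ threshold "
                        f"{options.prefilter_threshold:g}"
                    ),
                )
            )
            continue
        if options.mode == "per_symbol":
            rows = cs.row_sums
            for j, symbol in enumerate(cs.categories):
                sub = np.array(
                    [
                        [cs.counts[0, j], rows[0] - cs.counts[0, j]],
                        [cs.counts[1, j], rows[1] - cs.counts[1, j]],
                    ],
                    dtype=np.int64,
                )
                tested_idx.append(len(results))
                results.append(
                    AssociationResult(
                        probe_id=probe_id,
                        tested_symbol=symbol,
                        table=sub,
                        p_raw=fisher_exact_2x2(sub),
                    )
                )
        else:
            tested_idx.append(len(results))
            results.append(
                AssociationResult(
                    probe_id=probe_id,
                    tested_symbol="omnibus",
                    table=cs.counts.copy(),
                    p_raw=fisher_exact_rxc(cs.counts),
                )
            )

    m = len(tested_idx)
    if m:
        raw = [results[i].p_raw for i in tested_idx]
        p_bonf = bonferroni(raw, m)  # type: ignore[arg-type]
        p_fdr = fdr_bh(raw)  # type: ignore[arg-type]
        for i, pb, pf in zip(tested_idx, p_bonf, p_fdr):
            results[i] = replace(results[i], p_bonferroni=pb, p_fdr=pf)
    return results


def sort_results(
    results: Sequence[AssociationResult], by: str = "p_value"
) -> list[AssociationResult]:
    """Order results ``by`` ``p_value`` or ``probe_id``.

    Ties on p break by probe id then symbol; prefiltered records sort last.
    """
    if by == "p_value":
        key = lambda r: (  # noqa: E731
            r.prefiltered,
            r.p_raw if r.p_raw is not None else math.inf,
            r.probe_id,
            r.tested_symbol or "",
        )
    elif by == "probe_id":
        key = lambda r: (r.probe_id, r.tested_symbol or "")  # noqa: E731
    else:
        raise ConfigurationError(f"unknown sort key {by!r}")
    return sorted(results, key=key)
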