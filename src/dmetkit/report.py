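"""Heatmap encoding, per-probe frequency summaries and result rendering.

The heatmap is an integer-coded probe × sample matrix: genotype symbols are
sorted lexicographically over the whole dataset and assigned codes 1..k,
NoCall is always 0, and samples are grouped by class (classes in
lexicographic order, original order preserved within a class).  Decoding
through the legend reproduces the calls exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .association import AssociationResult, sort_results
from .annotation import results_to_frame
from .errors import ConfigurationError
from .io import DmetDataset, NOCALL, canonicalize_genotype


@dataclass(frozen=True)
class CodedMatrix:
    """Integer-coded genotype matrix plus the legend to invert it."""

    codes: np.ndarray  # shape (n_probes, n_samples), int
    legend: dict[int, str]  # code -> genotype symbol (1..k)
    probe_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]  # grouped by class
    class_labels: dict[str, str]
    nocall_code: int = 0


def encode_heatmap(dataset: DmetDataset) -> CodedMatrix:
    """Encode *dataset* as a :class:`CodedMatrix` (see module docstring)."""
    if dataset.n_probes == 0 or dataset.n_samples == 0:
        raise ValueError("cannot encode an empty dataset")
    order = sorted(
        range(dataset.n_samples),
        key=lambda i: (dataset.class_labels[dataset.sample_ids[i]], i),
    )
    sample_ids = tuple(dataset.sample_ids[i] for i in order)

    symbols = sorted(
        {str(c) for row in dataset.calls for c in row if not c.is_nocall}
    )
    legend = {code: sym for code, sym in enumerate(symbols, start=1)}
    sym_to_code = {sym: code for code, sym in legend.items()}

    codes = np.zeros((dataset.n_probes, dataset.n_samples), dtype=np.int64)
    for r, row in enumerate(dataset.calls):
        for c, i in enumerate(order):
            call = row[i]
            codes[r, c] = 0 if call.is_nocall else sym_to_code[str(call)]
    return CodedMatrix(
        codes=codes,
        legend=legend,
        probe_ids=tuple(dataset.probe_ids),
        sample_ids=sample_ids,
        class_labels=dict(dataset.class_labels),
    )


def decode_heatmap(coded: CodedMatrix) -> DmetDataset:
    """Invert :func:`encode_heatmap` (sample order is the grouped order)."""
    calls = [
        [
            NOCALL if code == coded.nocall_code
            else canonicalize_genotype(coded.legend[int(code)])
            for code in row
        ]
        for row in coded.codes
    ]
    return DmetDataset(
        probe_ids=list(coded.probe_ids),
        sample_ids=list(coded.sample_ids),
        calls=calls,
        class_labels=dict(coded.class_labels),
    )


def frequency_summary(
    dataset: DmetDataset, class_a: str, class_b: str
) -> pd.DataFrame:
    """Within-class relative genotype frequencies per probe.

    One row per (probe, class, symbol) over the union of symbols observed at
    the probe; NoCall is excluded from denominators.  A class with no
    measured genotype at a probe gets NaN frequencies (undefined).
    """
    for cls in (class_a, class_b):
        if cls not in set(dataset.class_labels.values()):
            raise ConfigurationError(f"class {cls!r} not present in dataset")
    idx_of = {s: i for i, s in enumerate(dataset.sample_ids)}
    class_cols = {
        cls: [idx_of[s] for s in dataset.samples_of(cls)]
        for cls in (class_a, class_b)
    }
    rows = []
    for pid, row in zip(dataset.probe_ids, dataset.calls):
        per_class: dict[str, dict[str, int]] = {}
        totals: dict[str, int] = {}
        for cls, cols in class_cols.items():
            counts: dict[str, int] = {}
            for i in cols:
                call = row[i]
                if call.is_nocall:
                    continue
                counts[str(call)] = counts.get(str(call), 0) + 1
            per_class[cls] = counts
            totals[cls] = sum(counts.values())
        symbols = sorted(set(per_class[class_a]) | set(per_class[class_b]))
        for cls in (class_a, class_b):
            for sym in symbols:
                freq = (
                    per_class[cls].get(sym, 0) / totals[cls]
                    if totals[cls] > 0
                    else float("nan")
                )
                rows.append(
                    {"probe_id": pid, "class_name": cls, "symbol": sym,
                     "frequency": freq}
                )
    return pd.DataFrame(
        rows, columns=["probe_id", "class_name", "symbol", "frequency"]
    )


def allele_frequency_summary(
    dataset: DmetDataset, class_a: str, class_b: str
) -> pd.DataFrame:
    """Per-allele (A/C/G/T/-) within-class frequencies, two alleles per call."""
    for cls in (class_a, class_b):
        if cls not in set(dataset.class_labels.values()):
            raise ConfigurationError(f"class {cls!r} not present in dataset")
    idx_of = {s: i for i, s in enumerate(dataset.sample_ids)}
    class_cols = {
        cls: [idx_of[s] for s in dataset.samples_of(cls)]
        for cls in (class_a, class_b)
    }
    rows = []
    for pid, row in zip(dataset.probe_ids, dataset.calls):
        for cls, cols in class_cols.items():
            counts: dict[str, int] = {}
            total = 0
            for i in cols:
                call = row[i]
                if call.is_nocall:
                    continue
                for allele in (call.allele1, call.allele2):
                    counts[allele] = counts.get(allele, 0) + 1
                    total += 1
            for allele in sorted(counts):
                rows.append(
                    {"probe_id": pid, "class_name": cls, "allele": allele,
                     "frequency": counts[allele] / total}
                )
    return pd.DataFrame(
        rows, columns=["probe_id", "class_name", "allele", "frequency"]
    )


def render_results(
    results: Sequence[AssociationResult], sort: str = "p_value"
) -> pd.DataFrame:
    """Results table ordered by ``p_value`` or ``probe_id``.

    Ties on p-value break by probe id then symbol; prefiltered rows sort
    last.  Unknown sort keys raise :class:`ConfigurationError`.
    """
    return results_to_frame(sort_results(results, by=sort))


def write_results_tsv(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def write_heatmap_tsvs(
    coded: CodedMatrix, codes_path: str | Path, legend_path: str | Path
) -> None:
    """Write the coded matrix and its legend as TSVs."""
    frame = pd.DataFrame(
        coded.codes, index=list(coded.probe_ids), columns=list(coded.sample_ids)
    )
    frame.index.name = "ProbeID"
    frame.to_csv(codes_path, sep="\t")
    with open(legend_path, "w", encoding="utf-8") as fh:
        fh.write("code\tsymbol\n")
        fh.write(f"{coded.nocall_code}\tNoCall\n")
        for code in sorted(coded.legend):
            fh.write(f"{code}\t{coded.legend[code]}\n")


def plot_heatmap(coded: CodedMatrix, path: str | Path, cmap: str = "viridis") -> None:
    """Render the coded matrix as an image with the legend on the colorbar."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n_codes = len(coded.legend) + 1
    fig, ax = plt.subplots(
        figsize=(max(4.0, 0.12 * len(coded.sample_ids)), max(3.0, 0.02 * len(coded.probe_ids)))
    )
    im = ax.imshow(coded.codes, aspect="auto", cmap=plt.get_cmap(cmap, n_codes),
                   vmin=-0.5, vmax=n_codes - 0.5, interpolation="nearest")
    ax.set_xlabel("samples (grouped by class)")
    ax.set_ylabel("probes")
    cbar = fig.colorbar(im, ax=ax, ticks=range(n_codes))
    cbar.ax.set_yticklabels(
        ["NoCall"] + [coded.legend[c] for c in sorted(coded.legend)]
    )
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
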