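"""Offline probe annotation and deterministic database-link construction.

Annotations live in a simple TSV (``probe_id``, ``rsid``, ``gene``, ``note``)
standing in for the vendor annotation library.  Links to dbSNP and PharmGKB
are built purely syntactically — no network access anywhere.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence
from urllib.parse import quote

import pandas as pd

from .association import AssociationResult
from .errors import ValidationError

RSID_RE = re.compile(r"^rs[0-9]+$")

DBSNP_BASE = "https://www.ncbi.nlm.nih.gov/snp/"
PHARMGKB_SEARCH = "https://www.pharmgkb.org/search?query="


@dataclass(frozen=True)
class AnnotationRecord:
    probe_id: str
    rsid: str = ""
    gene: str = ""
    note: str = ""


class AnnotationStore:
    """Probe-keyed collection of :class:`AnnotationRecord`."""

    def __init__(self, records: Sequence[AnnotationRecord] = ()):
        self._by_probe: dict[str, AnnotationRecord] = {}
        for rec in records:
            if rec.probe_id in self._by_probe:
                raise ValidationError(f"duplicate probe_id {rec.probe_id!r}")
            if rec.rsid and not RSID_RE.match(rec.rsid):
                warnings.warn(
                    f"probe {rec.probe_id!r}: malformed rsid {rec.rsid!r} blanked",
                    stacklevel=2,
                )
                rec = AnnotationRecord(rec.probe_id, "", rec.gene, rec.note)
            self._by_probe[rec.probe_id] = rec

    def get(self, probe_id: str) -> AnnotationRecord | None:
        return self._by_probe.get(probe_id)

    def __contains__(self, probe_id: str) -> bool:
        return probe_id in self._by_probe

    def __len__(self) -> int:
        return len(self._by_probe)


def load_annotation(path: str | Path) -> AnnotationStore:
    """Load an annotation TSV; unknown columns are ignored, missing optional
    fields allowed.  Duplicate probe ids raise :class:`ValidationError`."""
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "probe_id" not in frame.columns:
        raise ValidationError(f"{path}: annotation file lacks a 'probe_id' column")
    records = [
        AnnotationRecord(
            probe_id=row["probe_id"].strip(),
            rsid=row.get("rsid", "").strip(),
            gene=row.get("gene", "").strip(),
            note=row.get("note", "").strip(),
        )
        for _, row in frame.iterrows()
    ]
    return AnnotationStore(records)


def dbsnp_url(rsid: str) -> str:
    """dbSNP reference-SNP page URL for a valid ``rs<digits>`` identifier."""
    if not isinstance(rsid, str) or not RSID_RE.match(rsid):
        raise ValueError(f"malformed rsid {rsid!r} (expected rs<digits>)")
    return DBSNP_BASE + rsid


def pharmgkb_url(query: str) -> str:
    """PharmGKB search URL for an rsID or gene symbol."""
    if not isinstance(query, str) or not query.strip():
        raise ValueError("PharmGKB query must be a non-empty string")
    return PHARMGKB_SEARCH + quote(query.strip(), safe="")


def results_to_frame(results: Sequence[AssociationResult]) -> pd.DataFrame:
    """Flatten association results into the canonical results table."""
    rows = []
    for r in results:
        counts_a = counts_b = ""
        if r.table is not None:
            counts_a = ",".join(str(int(c)) for c in r.table[0])
            counts_b = ",".join(str(int(c)) for c in r.table[1])
        rows.append(
            {
                "probe_id": r.probe_id,
                "symbol": r.tested_symbol or "",
                "counts_a": counts_a,
                "counts_b": counts_b,
                "p_raw": r.p_raw,
                "p_bonferroni": r.p_bonferroni,
                "p_fdr": r.p_fdr,
                "prefiltered": r.prefiltered,
            }
        )
    columns = [
        "probe_id",
        "symbol",
        "counts_a",
        "counts_b",
        "p_raw",
        "p_bonferroni",
        "p_fdr",
        "prefiltered",
    ]
    return pd.DataFrame(rows, columns=columns)


def annotate_results(
    results: Sequence[AssociationResult], store: AnnotationStore
) -> pd.DataFrame:
    """Attach rsid/gene and dbSNP/PharmGKB URLs to each result row.

    Best-effort by design: probes missing from the store pass through with
    empty annotation fields; p-values, counts and row order never change.
    """
    frame = results_to_frame(results)
    rsids, genes, dbsnp, pharmgkb = [], [], [], []
    for probe_id in frame["probe_id"]:
        rec = store.get(probe_id)
        rsid = rec.rsid if rec else ""
        gene = rec.gene if rec else ""
        rsids.append(rsid)
        genes.append(gene)
        dbsnp.append(dbsnp_url(rsid) if rsid else "")
        query = rsid or gene
        pharmgkb.append(pharmgkb_url(query) if query else "")
    frame["rsid"] = rsids
    frame["gene"] = genes
    frame["dbsnp_url"] = dbsnp
    frame["pharmgkb_url"] = pharmgkb
    return frame
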