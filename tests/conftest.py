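from __future__ import annotations

import pytest
from hypothesis import settings

from dmetkit import DmetDataset, canonicalize_genotype

settings.register_profile("suite", derandomize=True, max_examples=60, deadline=None)
settings.load_profile("suite")


#: The worked four-probe example: two classes of two subjects each, with one
#: perfectly separated probe (Probe1), one mixed probe (Probe2), one
#: invariant probe (Probe3) and one near-invariant probe (Probe4).
TABLE1_ROWS = {
    "Probe1": ["C/C", "C/C", "T/T", "T/T"],
    "Probe2": ["G/C", "C/C", "-/T", "A/A"],
    "Probe3": ["C/T", "C/T", "C/T", "C/T"],
    "Probe4": ["G/G", "A/G", "G/G", "G/G"],
}


def make_table1_dataset() -> DmetDataset:
    samples = ["Subject1", "Subject2", "Subject3", "Subject4"]
    return DmetDataset(
        probe_ids=list(TABLE1_ROWS),
        sample_ids=samples,
        calls=[[canonicalize_genotype(c) for c in row] for row in TABLE1_ROWS.values()],
        class_labels={"Subject1": "A", "Subject2": "A", "Subject3": "B", "Subject4": "B"},
    )


@pytest.fixture
def table1_dataset() -> DmetDataset:
    return make_table1_dataset()


@pytest.fixture
def table1_tsv(tmp_path):
    path = tmp_path / "table1.tsv"
    lines = ["ProbeID\tSubject1\tSubject2\tSubject3\tSubject4", "Class\tA\tA\tB\tB"]
    for pid, cells in TABLE1_ROWS.items():
        lines.append("\t".join([pid, *cells]))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path
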