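"""Case-control association on a tiny genotype table.

Builds the four-probe worked example (two classes of two subjects), runs
the per-symbol Fisher workflow and prints the ranked results table.
"""

import pathlib
import tempfile

from dmetkit import AnalysisOptions, analyze, read_dmet_table, render_results

TABLE = """\
ProbeID\tSubject1\tSubject2\tSubject3\tSubject4
Class\tA\tA\tB\tB
Probe1\tC/C\tC/C\tT/T\tT/T
Probe2\tG/C\tC/C\t-/T\tA/A
Probe3\tC/T\tC/T\tC/T\tC/T
Probe4\tG/G\tA/G\tG/G\tG/G
"""

with tempfile.TemporaryDirectory() as tmp:
    path = pathlib.Path(tmp) / "table.tsv"
    path.write_text(TABLE)
    dataset = read_dmet_table(path)

results = analyze(dataset, AnalysisOptions(class_a="A", class_b="B"))
table = render_results(results, sort="p_value")
print(table.to_string(index=False))
print()
print(
    "Probe1 separates the classes perfectly (C/C in class A, T/T in class B);\n"
    "its 2x2 Fisher test over margins (2,2)/(2,2) gives p = 1/3 — the smallest\n"
    "p-value four samples can produce here — so it ranks first.  Probe3 is\n"
    "identical in both classes and gets p = 1."
)
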