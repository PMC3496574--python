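"""Plant associated markers in a synthetic chip and recover them.

Generates a 500-probe dataset (5 planted, completely separated between the
classes; the rest null) at a 13 vs 13 cohort scale, runs the association
workflow and checks that the planted probes top the ranking.
"""

import math

from dmetkit import AnalysisOptions, analyze, generate_dataset

dataset, truth = generate_dataset(
    m_null=495, m_assoc=5, n_class_a=13, n_class_b=13, effect=1.0, seed=7
)
results = analyze(dataset, AnalysisOptions(class_a="A", class_b="B"))

best: dict[str, tuple[float, float]] = {}
for r in results:
    if r.p_raw is not None and r.p_raw < best.get(r.probe_id, (math.inf,))[0]:
        best[r.probe_id] = (r.p_raw, r.p_fdr)

ranking = sorted(best, key=lambda pid: (best[pid][0], pid))
planted = set(truth.associated_ids)

print(f"planted probes: {sorted(planted)}")
print("top 8 probes by raw p-value:")
for pid in ranking[:8]:
    raw, fdr = best[pid]
    tag = "PLANTED" if pid in planted else "null"
    print(f"  {pid}  p_raw={raw:.3g}  p_fdr={fdr:.3g}  [{tag}]")

recovered = planted & set(ranking[: len(planted)])
print()
print(
    f"{len(recovered)}/{len(planted)} planted probes occupy the top "
    f"{len(planted)} ranks; each completely separated probe has "
    "p = 1/C(26,13) ~ 9.6e-8, orders of magnitude below anything a null\n"
    "probe produces at this sample size, and all survive BH at 0.05."
)
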