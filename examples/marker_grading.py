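"""Grade candidate diagnostic markers on a validation panel.

Two donors carry the QTL, five elite recipients do not.  Marker m1
misses one donor (false negative), m2 calls three recipients positive
(false positives), m3 agrees with the truth everywhere.  Ranking puts
the false-positive-free markers first: a false positive wastes
selection effort on lines that never had the gene.
"""

from masplan import MarkerSpec, generate_panel, mas_success_matrix, rank_markers

panel = generate_panel(
    n_donors=2,
    n_recipients=5,
    markers={
        "m1": MarkerSpec(fnr=0.5),
        "m2": MarkerSpec(fpr=0.6),
        "m3": MarkerSpec(),
    },
    seed=42,
)

print("Ranked marker accuracies (best first):")
for acc in rank_markers(panel):
    print(f"  {acc.marker_id}: FPR={acc.fpr:.0%} FNR={acc.fnr:.0%} "
          f"call rate={acc.call_rate:.0%}")

for marker in ("m1", "m3"):
    pred = mas_success_matrix(panel, marker)
    print(f"\nMAS with {marker} succeeds in {pred.n_success} of "
          f"{pred.n_crosses} donor x recipient crosses "
          f"({pred.success_fraction:.0%}):")
    print(pred.matrix)
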