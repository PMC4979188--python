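"""The Audic-Claverie exact test on tag counts from two libraries.

For a gene observed x times in a library of N1 clean tags and y times
in a library of N2 clean tags, the test asks whether the two relative
abundances differ.  Printed: the two-sided p-value and the log2 TPM
ratio used for effect-size filtering.
"""

from dgetag import ac_pvalue, bh_adjust, log2_ratio

cases = [
    (10, 100_000, 12, 100_000),   # near-identical abundance
    (10, 100_000, 40, 100_000),   # fourfold shift
    (0, 100_000, 25, 100_000),    # presence/absence
    (600, 6_000_000, 100, 1_000_000),  # equal TPM at unequal depths
]

print(f"{'x':>5} {'N1':>9} {'y':>5} {'N2':>9} {'p':>12} {'log2 ratio':>10}")
for x, n1, y, n2 in cases:
    p = ac_pvalue(x, n1, y, n2)
    lfc = log2_ratio(x, n1, y, n2)
    print(f"{x:>5} {n1:>9} {y:>5} {n2:>9} {p:>12.3e} {lfc:>10.2f}")

# Benjamini-Hochberg turns per-gene p-values into FDR estimates; the
# screen calls a gene only when fdr < 0.001 AND |log2 ratio| > 1
ps = [ac_pvalue(x, n1, y, n2) for x, n1, y, n2 in cases]
print("BH-adjusted:", [f"{q:.3e}" for q in bh_adjust(ps)])
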