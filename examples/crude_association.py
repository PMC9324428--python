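"""Crude association statistics straight from published genotype counts.

Rebuilds the case/control genotype tables of a candidate-SNP study
(CC/CA/AA = 285/236/58 cases, 538/502/105 controls), checks both groups for
Hardy-Weinberg equilibrium, and computes the chromosome-level allele-contrast
odds ratio. An OR below 1 would mean the minor A allele is less frequent in
cases; here the CI straddles 1, i.e. no overall association.
"""

from snp_epistat import Counts2x2, GenotypeCounts, allele_counts, crude_or, hwe_chi_square

cases = GenotypeCounts(285, 236, 58, group_label="cases")
controls = GenotypeCounts(538, 502, 105, group_label="controls")

for g in (cases, controls):
    c, a = allele_counts(g)
    hwe = hwe_chi_square(g)
    print(
        f"{g.group_label}: n={g.n}, minor-allele freq {100 * a / (a + c):.2f}%, "
        f"HWE chi2={hwe.chi2:.2f} (p={hwe.p:.2f})"
    )

(c1, a1), (c0, a0) = allele_counts(cases), allele_counts(controls)
res = crude_or(Counts2x2(a=a1, b=c1, c=a0, d=c0))
print(
    f"allele contrast (A vs C): OR={res.or_hat:.2f} "
    f"(95% CI {res.ci_low:.2f}-{res.ci_high:.2f}), p={res.p:.2f}"
)
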