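"""Case-control allele association from genotype counts.

Uses a 30+30 design with genotype counts 2/11/17 vs 1/3/26 (mm/Mm/MM).
Reports the minor-allele frequency ratio with its Katz 95% CI (the headline
statistic), the complementary major-allele line, the Pearson allele test,
the Woolf-CI odds ratio, and the dominant-model Fisher exact test.
"""

from neuromarker import GenotypeTable, associate

table = GenotypeTable(
    snp="rs_example", minor="G", major="C",
    counts={"case": (2, 11, 17), "control": (1, 3, 26)},
)
res = associate(table)

pct = res.percent_strings
print(f"minor allele: cases {pct['case']['minor']}% vs "
      f"controls {pct['control']['minor']}%")
print(f"frequency ratio {res.allele_ratio:.3f} "
      f"(95% CI {res.ci95[0]:.3f}-{res.ci95[1]:.3f}), "
      f"allele p = {res.allele_p:.3f}")
print(f"major-allele ratio {res.major_ratio:.3f} "
      f"(95% CI {res.major_ci95[0]:.3f}-{res.major_ci95[1]:.3f})")
print(f"odds ratio (Woolf) {res.odds_ratio:.3f} "
      f"(95% CI {res.odds_ci95[0]:.3f}-{res.odds_ci95[1]:.3f})")
print(f"dominant-model Fisher p = {res.dominant_p:.4f}")
# A frequency ratio of 3 with a CI excluding 1 marks the minor allele as a
# risk factor; the odds ratio (3.667) is reported separately because the two
# statistics are often conflated in association tables.
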