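"""Per-sample and per-file variant summary in one streaming pass.

Counts variant categories (SNP/INDEL/SV/MNP), multiallelic sites, and
genotype states (het, hom-alt, missing) for every sample, attributing a
record to a sample only when it carries a called non-reference allele.
"""

import tempfile
from pathlib import Path

from vcfbox import FixtureConfig, generate, vcfsummary

with tempfile.TemporaryDirectory() as d:
    text, _ = generate(FixtureConfig(seed=13, n_samples=4, n_variants=1000))
    vcf = Path(d) / "cohort.vcf"
    vcf.write_text(text)

    report = vcfsummary(str(vcf))
    print(report.pretty())

# The header lines give file-level totals (records per contig and per
# category); the table below them gives, per sample, how many carried
# variants fall in each category and how many genotypes are
# heterozygous, homozygous-alternate, or missing.
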