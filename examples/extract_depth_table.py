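"""Extract one FORMAT item (read depth) as a typed samples x variants matrix.

The table loader reads exactly one FORMAT item per pass, returning an
integer matrix rather than text, plus the per-site columns.  Here it is
restricted to three samples and to PASS SNPs, with the INFO block dropped.
"""

import tempfile
from pathlib import Path

from vcfbox import FixtureConfig, generate, vcftable

with tempfile.TemporaryDirectory() as d:
    text, truth = generate(FixtureConfig(seed=11, n_samples=8, n_variants=300))
    vcf = Path(d) / "cohort.vcf"
    vcf.write_text(text)

    table = vcftable(str(vcf), samples=["S3", "S1", "S5"], format_item="DP",
                     snp_only=True, pass_only=True, drop_info=True)
    print(f"kept {table.n_variants} PASS SNP sites; "
          f"matrix {table.matrix.shape} dtype {table.matrix.dtype}")
    print(table.to_tsv().splitlines()[0])
    for line in table.to_tsv().splitlines()[1:4]:
        print(line)

# The matrix holds per-sample read depths as integers (missing = -1);
# rows of the TSV are sites that survived the filters, in file order,
# with one depth column per requested sample in the requested order.
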