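"""Shared fixtures: synthetic callsets written once per session.

All test inputs are generated programmatically; nothing is read from
checked-in data files.
"""

from __future__ import annotations

import pytest

from vcfbox import FixtureConfig, generate
from vcfbox.io import convert
from vcfbox.synth import adversarial_suite


@pytest.fixture(scope="session")
def small_fixture(tmp_path_factory):
    """20 samples × 400 variants on two contigs, in all three containers."""
    cfg = FixtureConfig(
        seed=101, n_samples=20, n_variants=400,
        contigs=(("chr21", 46_709_983), ("chr22", 50_818_468)),
    )
    text, truth = generate(cfg)
    d = tmp_path_factory.mktemp("small")
    vcf = d / "small.vcf"
    vcf.write_text(text)
    gz = d / "small.vcf.gz"
    bcf = d / "small.bcf"
    convert(str(vcf), str(gz))
    convert(str(vcf), str(bcf))
    return {
        "config": cfg, "text": text, "truth": truth,
        "vcf": str(vcf), "gz": str(gz), "bcf": str(bcf),
    }


@pytest.fixture(scope="session")
def adversarial_files(tmp_path_factory):
    """The hand-built edge-case VCFs, written to disk, keyed by name."""
    d = tmp_path_factory.mktemp("adversarial")
    out = {}
    for name, text in adversarial_suite():
        p = d / f"{name}.vcf"
        p.write_text(text)
        out[name] = str(p)
    return out
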