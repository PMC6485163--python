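"""Plant a run of homozygosity, write VCF+BED, and call it back.

The caller bins the callable genome into 1-kbp windows, marks a window
low-heterozygosity when it has strictly less than 10% of the expected
1 het/kbp, and reports maximal runs spanning more than 0.5/1/1.5 Mbp with
at least 67% of the span callable.
"""

import tempfile
from pathlib import Path

from ghostabc.dataio import read_bed_mask, read_vcf
from ghostabc.stats import call_roh
from ghostabc.synthetic import make_roh_genome

with tempfile.TemporaryDirectory() as tmp:
    out = Path(tmp)
    manifest = make_roh_genome(
        out,
        planted_segments=[(2_000_000, 4_000_000)],
        genome_length=8_000_000,
        background_het_per_kbp=1.0,
        rng_seed=5,
    )
    print(f"planted: {manifest['planted_segments']}, "
          f"{manifest['n_het_sites']} het sites elsewhere")
    mask = read_bed_mask(out / "mask.bed")
    geno = read_vcf(out / "genome.vcf", ["sample1"], mask)
    het = geno.positions[geno.dosages[:, 0] == 1]
    for seg in call_roh({"frag0": het}, mask):
        print(f"called ROH {seg.contig}:{seg.start}-{seg.end} "
              f"({seg.length/1e6:.2f} Mbp, tier >= {seg.tier} Mbp, "
              f"{100*seg.callable_fraction:.0f}% callable)")
# The called segment should match the planted 2-4 Mbp region to ~1 kbp.
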