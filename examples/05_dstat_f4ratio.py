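"""ABBA-BABA D-statistic and f4-ratio on a planted-admixture panel.

Simulates a six-genome panel in which the African-like target X received a
30% pulse from the European-like donor Fr, then (1) tests for gene flow
with D(Yor, X; Fr, Outgroup) and (2) estimates the admixture proportion
with f4(Sar, Han; X, Yor) / f4(Sar, Han; Fr, Yor). Standard errors come
from a weighted block jackknife.
"""

from ghostabc.simulate import desk_fragments
from ghostabc.stats import d_statistic, f4_ratio
from ghostabc.synthetic import make_admixed_panel

geno, manifest = make_admixed_panel(
    0.3, fragments=desk_fragments(400, 20_000), rng_seed=0
)
print(f"panel: {manifest['panel']}, planted alpha = {manifest['alpha']}")

d = d_statistic(geno, "Yor", "X", "Fr", "O", block_size=250_000, rng_seed=1)
print(f"D(Yor, X; Fr, O) = {d.d:.3f} +- {d.se:.3f}  (Z = {d.z:.1f}, "
      f"{d.abba} ABBA / {d.baba} BABA sites)")

f4 = f4_ratio(
    geno, ("Sar", "Han", "X", "Yor"), ("Sar", "Han", "Fr", "Yor"),
    block_size=250_000, rng_seed=1,
)
print(f"f4-ratio admixture estimate: {100*f4.alpha:.1f}% +- {100*f4.se:.1f}%")
# Z >> 3 signals gene flow; the ratio should bracket the planted 30%.
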