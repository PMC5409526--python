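"""Measure single-exon spike-in sensitivity.

For a handful of exons, repeatedly scales one random sample's coverage at
that exon by 0.5 (deletion) or 1.5 (duplication), re-calls the sample, and
reports the percentage of repeats in which a matching call overlapped the
spiked exon.  Single-exon events are the hardest class: duplications change
coverage by a smaller relative margin than deletions, so their sensitivity
is expected to be slightly lower.  (Repeats are kept small here so the
script runs in seconds; increase `reps` for a full study.)
"""

from exoncnv import SimSpec, make_panel, simulate_pool
from exoncnv.simulate import single_exon_sensitivity

panel, _ = make_panel(seed=1)
pool, _ = simulate_pool(SimSpec(n_samples=48, seed=1), panel)

exons = [2, 10, 25, 40]
for kind in ["deletion", "duplication"]:
    sens = single_exon_sensitivity(pool, exons, kind=kind, reps=25, seed=7)
    print(f"{kind}s (25 repeats/exon):")
    for t, value in sens.items():
        target = panel[t]
        print(f"  {target.gene} exon {target.custom_number:2d}: {value:5.1f}%")
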