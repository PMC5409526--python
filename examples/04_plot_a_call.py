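"""Render the two-panel evidence plot for a called CNV.

Top panel: log-normalised coverage of the test sample (blue) against its
chosen reference samples (grey) — a CNV shows as a localised departure from
the shared profile.  Bottom panel: per-exon observed/expected read ratio
with the pointwise 95% interval implied by the fitted beta-binomial at
normal copy number; called exons are highlighted in red and should fall
clearly outside the band.
"""

from pathlib import Path

from exoncnv import (
    Implant,
    SimSpec,
    call_sample,
    make_panel,
    plot_call,
    select_reference,
    simulate_pool,
)

panel, _ = make_panel(seed=1)
spec = SimSpec(
    n_samples=48, seed=3, implants=(Implant(4, "GENEA", 7, 9, "deletion"),)
)
matrix, truth = simulate_pool(spec, panel)
sample = truth[0].sample

calls, _ = call_sample(matrix, sample)
selection, fit = select_reference(matrix, sample)
out = Path("scratch") / "example_plots"
out.mkdir(parents=True, exist_ok=True)
for i, call in enumerate(calls):
    path = out / f"call_{i + 1}_{sample}.png"
    plot_call(call, matrix, selection, fit, path)
    print(f"{call.cnv_type} {call.chrom}:{call.genomic_start}-{call.genomic_end} -> {path}")
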