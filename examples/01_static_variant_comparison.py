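"""Compare the local surface potential of a toy variant against wild type.

Builds a 20-residue toy protein, flips two elementary charges at residue 7
(a K->D-like substitution), and runs the full static local comparison:
solvent-excluded surface, screened-Coulomb potential, 4-Angstrom region,
resampled t/KS/AD tests.
"""

import logging
import tempfile
from pathlib import Path

import surfdelta as sd

logging.basicConfig(level=logging.WARNING)

d = Path(tempfile.mkdtemp())
wt, _ = sd.make_toy_protein(sd.ToySpec(n_residues=20, seed=2))
site = sd.SiteSpec(chain_id="A", residue_number=7, wt_aa="K", mut_aa="D")
mut = sd.make_mutant(wt, site, delta_charge=-2.0)
sd.write_pqr(wt, d / "wt.pqr")
sd.write_pqr(mut, d / "mut.pqr")

report = sd.run_compare(sd.RunConfig(
    wt_pqr=str(d / "wt.pqr"), mut_pqr=str(d / "mut.pqr"),
    mode="local", level="static", site=site,
    resampling=sd.ResamplingConfig(n_points=100, n_iterations=1000, seed=42),
))

r = report.result
print(f"variant {report.variant}: {r.n_wt} WT / {r.n_mut} variant region vertices")
print(f"median potential shift: {r.median_shift:+.3f} kBT/ec")
print(f"p_T  = {sd.format_p(r.p_t)}")
print(f"p_KS = {sd.format_p(r.p_ks)}")
print(f"p_AD = {sd.format_p(r.p_ad)}")
print(f"significant at alpha=0.01: {report.significant()}")
# A negative shift of several kBT/ec with a tiny p_AD: the -2e change makes
# the local surface clearly more electronegative, and the tail-sensitive
# AD test picks it up decisively.
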