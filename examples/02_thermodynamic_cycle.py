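"""Close a thermodynamic cycle: ddG of dimerization and folding.

Builds a three-leg synthetic study (alchemical modification in dimer,
monomer, and unfolded contexts), estimates each leg, and combines them:

    ddG_dimerization = dG_dim - 2 dG_mono   (positive = dimer destabilized)
    ddG_folding      = dG_mono - dG_unf     (positive = monomer destabilized)

Errors propagate in quadrature; effects smaller than 1 sigma are labelled
insignificant.  The convergence report compares per-lambda errors with 2RT.
"""

import tempfile

from ticycle.config import RunConfig
from ticycle.pipeline import estimate_all_legs, run_cycle, synth_study

config = RunConfig(seed=7)  # default: 25 nodes x 9 replicas x 500 ps per leg

with tempfile.TemporaryDirectory() as tmp:
    manifest = synth_study(config, tmp + "/study")
    estimates = estimate_all_legs(tmp + "/study", config)
    result = run_cycle(estimates, config)

for leg, est in estimates.items():
    truth = manifest["legs"][leg]["true_delta_g"]
    print(f"dG_{leg:<9s} = {est.delta_g:7.3f} +/- {est.sigma:.3f} kJ/mol "
          f"(truth {truth:.1f})")
ddg = result["ddg"]
print(f"ddG_dimerization = {ddg['ddg_dimerization_kj_mol']:.3f} +/- "
      f"{ddg['sigma_dimerization_kj_mol']:.3f} kJ/mol "
      f"[{ddg['class_dimerization']}]  (truth {manifest['true_ddg_dimerization']:.1f})")
print(f"ddG_folding      = {ddg['ddg_folding_kj_mol']:.3f} +/- "
      f"{ddg['sigma_folding_kj_mol']:.3f} kJ/mol "
      f"[{ddg['class_folding']}]  (truth {manifest['true_ddg_folding']:.1f})")
conv = result["convergence"]
print(f"mean per-lambda SEM = {conv['mean_sem_kj_mol']:.2f} kJ/mol; "
      f"2RT reference = {conv['thermal_reference_2rt_kj_mol']:.2f} kJ/mol")
# Positive ddG means the modification destabilizes the dimer (monomer);
# per-lambda SEMs well below 2RT indicate converged sampling.
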