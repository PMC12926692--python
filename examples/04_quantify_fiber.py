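"""Full per-fiber quantification: isoform ratios, proteoforms, P_total.

Runs the complete MS1 pipeline on a noisy hybrid-fiber run and compares
the three reported statistics against the generator's ground truth.
"""

from fiberform import (
    AnalysisConfig,
    fiber_report,
    generate_run,
    mock_target_table,
    fiber_fixture,
)
from fiberform.synthetic_data import FAMILIES

config = fiber_fixture("hybrid_fiber", seed=7)
run, manifest = generate_run(config)
analysis = AnalysisConfig(families={k: list(v) for k, v in FAMILIES.items()},
                          charge_range=(8, 50))
report = fiber_report(run, mock_target_table(), analysis, fiber_id="demo")

print("isoform relative abundance (estimate | truth):")
for family, fracs in sorted(report.isoform_ratios.items()):
    for protein, frac in sorted(fracs.items()):
        truth = manifest.isoform_fractions[family].get(protein, 0.0)
        print(f"  {family:6s} {protein:8s} {frac:6.3f} | {truth:6.3f}")

print("\ntotal phosphorylation, mol Pi / mol protein (estimate | truth):")
for protein in ("aTpm", "bTpm", "MLC2S", "MLC2F"):
    print(f"  {protein:6s} {report.total_phosphorylation[protein]:6.3f} "
          f"| {manifest.total_phosphorylation[protein]:6.3f}")

print(f"\nMLC3F/MLC1F AUC ratio: "
      f"{report.pairwise_ratios['MLC3F/MLC1F']:.3f}")
print("MLC2S proteoform fractions (note the +29.0 Da satellite):")
for pid, frac in sorted(report.proteoform_abundances["MLC2S"].items()):
    print(f"  {pid:22s} {frac:.3f}")
print("\nEstimates within ~0.01-0.02 of truth demonstrate the pipeline "
      "recovers fiber composition from raw spectra.")
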