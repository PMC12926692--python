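"""Deconvolute an averaged spectrum into neutral masses, two ways.

A noise-free run of one 18 kDa protein with an unmodified and a
mono-phosphorylated form is averaged across the elution peak, then
deconvoluted with (a) the isotopically resolved route (spacing-based
charge inference + averagine validation) and (b) iterative nonnegative
envelope deconvolution onto a zero-charge mass grid.
"""

from fiberform import (
    ProteoformSpec,
    average_spectra,
    envelope_deconvolute,
    generate_run,
    merge_charge_evidence,
    snap_monoisotopic,
)
from fiberform.synthetic_data import ProteoformSignal, SyntheticRunConfig

base = ProteoformSpec(id="P_0P", protein_name="P", gene="G",
                      base_neutral_mass=18000.0, phospho_sites_max=1)
mono = ProteoformSpec(id="P_1P", protein_name="P", gene="G",
                      base_neutral_mass=18000.0,
                      modifications=(("phospho", 1),), phospho_sites_max=1)
config = SyntheticRunConfig(
    proteoforms=[
        ProteoformSignal(spec=base, abundance=0.7, rt_center=3.0,
                         z_center=18.5, z_sigma=2.0),
        ProteoformSignal(spec=mono, abundance=0.3, rt_center=3.0,
                         z_center=18.5, z_sigma=2.0),
    ],
    rt_span=(0.0, 6.0))
run, manifest = generate_run(config)
averaged = average_spectra(run, (2.5, 3.5))

clusters, remainder = snap_monoisotopic(averaged, charge_range=(12, 25))
decon = merge_charge_evidence(clusters)
print("isotopic route (charge from isotopologue spacing):")
for p in sorted(decon.peaks, key=lambda p: -p.intensity):
    print(f"  M = {p.neutral_mass:12.4f} Da  I = {p.intensity:9.1f}  "
          f"charges {p.supporting_charges[0]}-{p.supporting_charges[-1]}  "
          f"score {p.score:.3f}")

decon2, grid, h = envelope_deconvolute(averaged, (17800.0, 18300.0),
                                       charge_range=(12, 25))
print("envelope route (iterative nonnegative deconvolution):")
for p in sorted(decon2.peaks, key=lambda p: -p.intensity)[:2]:
    print(f"  M = {p.neutral_mass:12.4f} Da  I = {p.intensity:9.2f}")
print("\nTrue masses: 18000.0000 (0P) and 18079.9663 (1P), 70/30 mixture; "
      "both routes should land within a few ppm and near the 7:3 ratio.")
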