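"""Synthetic single-fiber LC-MS run generator with ground truth.

Emulates the acquisition regime of a QTOF top-down run on single human
skeletal muscle fibers: MS1 centroid (or profile) spectra at 1 Hz over
300-3000 m/z, resolving power ~60 000, co-eluting fast/slow sarcomeric
isoforms between 5 and 60 kDa carrying charge envelopes of roughly 10-70
protons, with phospho satellites.  Every generated run comes with a
ground-truth manifest so downstream estimates can be scored exactly.

The bundled sarcomeric protein library is synthetic: protein names, genes
and phosphosite counts follow the muscle literature, but the neutral masses
are fixed mock values chosen to be plausible for each isoform, not database
values.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from .mass_model import (
    PROTON_MASS,
    ProteoformSpec,
    averagine_isotope_distribution,
    proteoform_mass,
)
from .spectra_io import CENTROID, PROFILE, Scan, SpectrumRun

__all__ = [
    "NoiseModel",
    "ProteoformSignal",
    "SyntheticRunConfig",
    "GroundTruthManifest",
    "auto_charge_envelope",
    "generate_run",
    "fiber_fixture",
    "mock_target_table",
    "MOCK_LIBRARY",
    "FAST_ISOFORMS",
    "FAMILIES",
]


@dataclass(frozen=True)
class NoiseModel:
    """Detector noise: additive baseline per peak, multiplicative log-normal
    intensity noise with the given CV, and Poisson-rate spurious peaks."""

    baseline_level: float = 0.0
    intensity_cv: float = 0.0
    spurious_peak_rate: float = 0.0  # expected spurious peaks per scan
    spurious_intensity: float = 50.0  # exponential scale of spurious peaks


@dataclass
class ProteoformSignal:
    """One simulated species: a proteoform, its abundance and elution.

    ``abundance`` is the within-family fraction; the family's overall ion
    current is set by ``SyntheticRunConfig.family_loadings``.  The charge
    envelope defaults to the mass-derived auto model when ``z_center`` is
    None.
    """

    spec: ProteoformSpec
    abundance: float
    rt_center: float
    rt_sigma: float = 0.15
    z_center: float | None = None
    z_sigma: float | None = None
    family: str | None = None

    @property
    def family_key(self) -> str:
        return self.family if self.family is not None else self.spec.protein_name


@dataclass
class SyntheticRunConfig:
    proteoforms: list[ProteoformSignal]
    seed: int = 0
    resolving_power: float = 60000.0
    mz_range: tuple[float, float] = (300.0, 3000.0)
    scan_rate_hz: float = 1.0
    rt_span: tuple[float, float] = (0.0, 12.5)
    mode: str = CENTROID
    quad_low_mass: float | None = None  # m/z transmission floor, if any
    noise: NoiseModel = field(default_factory=NoiseModel)
    family_loadings: dict[str, float] = field(default_factory=dict)
    total_intensity: float = 1.0e6
    truncate_at: float = 1e-4

    def __post_init__(self) -> None:
        if not self.proteoforms:
            raise ValueError("config needs at least one proteoform")
        if not self.mz_range[0] < self.mz_range[1]:
            raise ValueError("mz_range lower bound must be below upper bound")
        sums: dict[str, float] = {}
        for sig in self.proteoforms:
            sums[sig.family_key] = sums.get(sig.family_key, 0.0) + sig.abundance
        bad = {k: v for k, v in sums.items() if abs(v - 1.0) > 1e-9}
        if bad:
            raise ValueError(
                f"per-family abundances must sum to 1; off for {bad}")

    def loading(self, family: str) -> float:
        return self.family_loadings.get(family, 1.0)


def auto_charge_envelope(
    neutral_mass: float,
    mz_range: tuple[float, float] = (300.0, 3000.0),
) -> tuple[int, float]:
    """Mass-derived QTOF charge envelope (center charge, charge sigma).

    ``z_center = round(sqrt(M) / 4.5)``, nudged so the envelope apex m/z
    stays inside the acquisition range; ``z_sigma = max(1.5, z_center / 6)``.
    """
    z = max(1, round(math.sqrt(neutral_mass) / 4.5))
    lo, hi = mz_range
    while z > 1 and (neutral_mass + z * PROTON_MASS) / z < lo:
        z -= 1
    while (neutral_mass + z * PROTON_MASS) / z > hi:
        z += 1
    return z, max(1.5, z / 6.0)


def _charge_weights(
    z_center: float,
    z_sigma: float,
    apex_mz_of: "callable",
    mz_lo: float,
    mz_hi: float,
) -> tuple[np.ndarray, np.ndarray]:
    z_min = max(1, int(math.floor(z_center - 4 * z_sigma)))
    z_max = int(math.ceil(z_center + 4 * z_sigma))
    charges = np.arange(z_min, z_max + 1)
    weights = np.exp(-0.5 * ((charges - z_center) / z_sigma) ** 2)
    apex = np.array([apex_mz_of(z) for z in charges])
    keep = (apex >= mz_lo) & (apex <= mz_hi)
    charges, weights = charges[keep], weights[keep]
    if charges.size:
        weights = weights / weights.sum()
    return charges, weights


@dataclass
class GroundTruthManifest:
    """What was actually simulated, plus the derived per-protein truths.

    The derived blocks (isoform fractions, proteoform fractions, total
    phosphorylation) are recomputed from the per-proteoform amplitudes with
    the same formulas the quantification stage defines, so pipeline output
    can be compared entry by entry.
    """

    proteoforms: list[dict]
    isoform_fractions: dict[str, dict[str, float]]
    proteoform_fractions: dict[str, dict[str, float]]
    total_phosphorylation: dict[str, float]
    excluded: list[str]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    def proteoform(self, pid: str) -> dict:
        for p in self.proteoforms:
            if p["id"] == pid:
                return p
        raise KeyError(pid)


def _build_manifest(
    entries: list[dict],
    excluded: list[str],
) -> GroundTruthManifest:
    live = [e for e in entries if not e["excluded"]]
    iso: dict[str, dict[str, float]] = {}
    prot: dict[str, dict[str, float]] = {}
    for e in live:
        fam = iso.setdefault(e["family"], {})
        fam[e["protein_name"]] = fam.get(e["protein_name"], 0.0) + e["amplitude"]
        prot.setdefault(e["protein_name"], {})[e["id"]] = e["amplitude"]
    isoform_fractions = {
        fam: {p: a / sum(d.values()) for p, a in d.items()}
        for fam, d in iso.items()
    }
    proteoform_fractions = {
        p: {pid: a / sum(d.values()) for pid, a in d.items()}
        for p, d in prot.items()
    }
    total_phos = {}
    for p, d in prot.items():
        counts = {e["id"]: e["phospho_count"] for e in live
                  if e["protein_name"] == p}
        tot = sum(d.values())
        total_phos[p] = sum(counts[pid] * a for pid, a in d.items()) / tot
    return GroundTruthManifest(
        proteoforms=entries,
        isoform_fractions=isoform_fractions,
        proteoform_fractions=proteoform_fractions,
        total_phosphorylation=total_phos,
        excluded=excluded,
    )


def generate_run(
    config: SyntheticRunConfig,
) -> tuple[SpectrumRun, GroundTruthManifest]:
    """Render a synthetic LC-MS run and its ground-truth manifest.

    Each proteoform contributes a unit-area Gaussian elution profile scaled
    by ``total_intensity x family loading x abundance``, spread over a
    discretized Gaussian charge envelope; each charge carries the averagine
    isotope pattern of the proteoform's mass.  Centroid mode emits the exact
    isotopologue m/z values; profile mode renders each as a Gaussian of
    FWHM = m/z / resolving_power.  Deterministic for a fixed config+seed.
    """
    rng = np.random.default_rng(config.seed)
    mz_lo, mz_hi = config.mz_range
    floor = max(mz_lo, config.quad_low_mass or mz_lo)
    dt = 1.0 / (60.0 * config.scan_rate_hz)
    n_scans = int(round((config.rt_span[1] - config.rt_span[0]) / dt)) + 1
    times = config.rt_span[0] + dt * np.arange(n_scans)

    scan_mz: list[list[np.ndarray]] = [[] for _ in range(n_scans)]
    scan_int: list[list[np.ndarray]] = [[] for _ in range(n_scans)]
    entries: list[dict] = []
    excluded: list[str] = []

    for sig in config.proteoforms:
        mass = proteoform_mass(sig.spec)
        iso = averagine_isotope_distribution(mass, config.truncate_at)
        if sig.z_center is None:
            zc, zs = auto_charge_envelope(mass, (floor, mz_hi))
        else:
            zc = sig.z_center
            zs = sig.z_sigma if sig.z_sigma is not None else max(1.5, zc / 6.0)
        apex_mass = iso.most_abundant_mass

        def apex_mz(z: int, m: float = apex_mass) -> float:
            return (m + z * PROTON_MASS) / z

        charges, weights = _charge_weights(zc, zs, apex_mz, floor, mz_hi)
        amplitude = (config.total_intensity * config.loading(sig.family_key)
                     * sig.abundance)
        entry = {
            "id": sig.spec.id,
            "protein_name": sig.spec.protein_name,
            "gene": sig.spec.gene,
            "family": sig.family_key,
            "monoisotopic_mass": mass,
            "most_abundant_mass": apex_mass,
            "abundance": sig.abundance,
            "amplitude": amplitude,
            "rt_center": sig.rt_center,
            "rt_sigma": sig.rt_sigma,
            "charges": charges.tolist(),
            "charge_weights": weights.tolist(),
            "phospho_count": sig.spec.phospho_count,
            "excluded": False,
        }
        if charges.size == 0:
            warnings.warn(
                f"proteoform {sig.spec.id}: entire charge envelope falls "
                f"outside m/z range; excluded from the run")
            entry["excluded"] = True
            excluded.append(sig.spec.id)
            entries.append(entry)
            continue
        entries.append(entry)

        # flatten (charge, isotopologue) into one peak list
        mz_flat = ((iso.neutral_masses[None, :]
                    + charges[:, None] * PROTON_MASS) / charges[:, None])
        wt_flat = weights[:, None] * iso.probabilities[None, :]
        in_range = (mz_flat >= floor) & (mz_flat <= mz_hi)
        mz_flat = mz_flat[in_range]
        wt_flat = wt_flat[in_range]

        g = np.exp(-0.5 * ((times - sig.rt_center) / sig.rt_sigma) ** 2)
        gsum = g.sum()
        if gsum == 0:
            warnings.warn(
                f"proteoform {sig.spec.id}: elution profile outside rt span")
            continue
        g = g / gsum
        active = np.nonzero(g > 1e-9 * g.max())[0]
        for j in active:
            scan_mz[j].append(mz_flat)
            scan_int[j].append(amplitude * g[j] * wt_flat)

    noise = config.noise
    sigma_ln = math.sqrt(math.log(1.0 + noise.intensity_cv**2))
    mu_ln = -0.5 * sigma_ln**2  # unit-mean multiplicative noise

    scans: list[Scan] = []
    for j in range(n_scans):
        if scan_mz[j]:
            mz = np.concatenate(scan_mz[j])
            inten = np.concatenate(scan_int[j])
        else:
            mz = np.empty(0)
            inten = np.empty(0)
        if noise.intensity_cv > 0 and inten.size:
            inten = inten * rng.lognormal(mu_ln, sigma_ln, inten.size)
        if noise.baseline_level > 0 and inten.size:
            inten = inten + noise.baseline_level
        if noise.spurious_peak_rate > 0:
            k = rng.poisson(noise.spurious_peak_rate)
            if k:
                mz = np.concatenate([mz, rng.uniform(mz_lo, mz_hi, k)])
                inten = np.concatenate(
                    [inten, rng.exponential(noise.spurious_intensity, k)])
        order = np.argsort(mz, kind="stable")
        mz, inten = mz[order], inten[order]
        if config.mode == PROFILE:
            mz, inten = _render_profile(mz, inten, config.resolving_power)
        scans.append(Scan(rt=float(times[j]), mz=mz, intensity=inten,
                          mode=config.mode))

    run = SpectrumRun(scans=scans, instrument="synthetic-qtof",
                      mz_range=config.mz_range,
                      scan_rate_hz=config.scan_rate_hz)
    return run, _build_manifest(entries, excluded)


def _render_profile(
    mz: np.ndarray,
    intensity: np.ndarray,
    resolving_power: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Render centroids as Gaussians of FWHM = m/z / R on a sparse grid."""
    if mz.size == 0:
        return mz, intensity
    sigma = mz / resolving_power / 2.3548200450309493
    pieces = [m + np.linspace(-3.0, 3.0, 13) * s for m, s in zip(mz, sigma)]
    grid = np.unique(np.concatenate(pieces))
    y = np.zeros_like(grid)
    for m, s, h in zip(mz, sigma, intensity):
        a = np.searchsorted(grid, m - 4 * s)
        b = np.searchsorted(grid, m + 4 * s)
        y[a:b] += h * np.exp(-0.5 * ((grid[a:b] - m) / s) ** 2)
    return grid, y


# ---------------------------------------------------------------------------
# built-in sarcomeric mock library and fiber fixtures

#: protein -> (gene, mock monoisotopic mass Da, phospho sites, family,
#:             rt center min, fast isoform?)
#: Masses are synthetic placeholders in the 16-42 kDa range typical of the
#: thin-filament and myosin light chain proteins, not database values.
MOCK_LIBRARY: dict[str, tuple[str, float, int, str, float, bool]] = {
    "ssTnC":    ("TNNC1", 18403.0, 0, "TnC", 4.20, False),
    "fsTnC":    ("TNNC2", 18122.0, 0, "TnC", 4.80, True),
    "MLC2S":    ("MYL2", 18658.0, 2, "MLC2", 5.50, False),
    "MLC2F":    ("MYL11", 18969.0, 2, "MLC2", 6.10, True),
    "ssTnI":    ("TNNI1", 21693.0, 0, "TnI", 6.80, False),
    "fsTnI":    ("TNNI2", 21339.0, 0, "TnI", 7.40, True),
    "MLC1V":    ("MYL3", 21932.0, 0, "MLC1", 8.10, False),
    "MLC1F":    ("MYL1", 20863.0, 0, "MLC1", 8.70, True),
    "MLC3F":    ("MYL1", 16506.0, 0, "MLC1", 9.30, True),
    "bTpm":     ("TPM2", 32910.0, 2, "Tpm", 10.00, False),
    "aTpm":     ("TPM1", 32680.0, 2, "Tpm", 10.60, True),
    "sa-actin": ("ACTA1", 41785.0, 0, "actin", 11.40, False),
}

FAST_ISOFORMS = frozenset(p for p, v in MOCK_LIBRARY.items() if v[5])

FAMILIES: dict[str, list[str]] = {}
for _p, _v in MOCK_LIBRARY.items():
    FAMILIES.setdefault(_v[3], []).append(_p)

#: +29 Da satellite abundance (as a fraction of the MLC2S proteoform pool)
#: used when the unexplained-shift species is simulated
_MLC2S_SHIFT_DA = 29.0
_MLC2S_SHIFT_FRACTION = 0.06

#: within-protein proteoform splits: protein -> {phospho count -> fraction}
_PHOSPHO_SPLITS: dict[str, dict[int, float]] = {
    "aTpm": {0: 0.87, 1: 0.12, 2: 0.01},   # P_total 0.14
    "bTpm": {0: 0.92, 1: 0.08},            # P_total 0.08
    "MLC2F": {0: 0.70, 1: 0.28, 2: 0.02},  # P_total 0.32
    "MLC2S": {0: 0.72, 1: 0.28},           # P_total 0.28
}

#: per-family isoform splits for the three fiber archetypes
_FIBER_COMPOSITIONS: dict[str, dict[str, dict[str, float]]] = {
    "slow_fiber": {
        "TnC": {"ssTnC": 0.92, "fsTnC": 0.08},
        "MLC2": {"MLC2S": 0.95, "MLC2F": 0.05},
        "TnI": {"ssTnI": 0.95, "fsTnI": 0.05},
        "MLC1": {"MLC1V": 0.920, "MLC1F": 0.075, "MLC3F": 0.005},
        "Tpm": {"bTpm": 0.92, "aTpm": 0.08},
        "actin": {"sa-actin": 1.0},
    },
    "fast_fiber": {
        "TnC": {"ssTnC": 0.07, "fsTnC": 0.93},
        "MLC2": {"MLC2S": 0.05, "MLC2F": 0.95},
        "TnI": {"ssTnI": 0.05, "fsTnI": 0.95},
        "MLC1": {"MLC1V": 0.07, "MLC1F": 0.85, "MLC3F": 0.08},
        "Tpm": {"bTpm": 0.35, "aTpm": 0.65},
        "actin": {"sa-actin": 1.0},
    },
    "hybrid_fiber": {
        "TnC": {"ssTnC": 0.50, "fsTnC": 0.50},
        "MLC2": {"MLC2S": 0.50, "MLC2F": 0.50},
        "TnI": {"ssTnI": 0.45, "fsTnI": 0.55},
        "MLC1": {"MLC1V": 0.40, "MLC1F": 0.55, "MLC3F": 0.05},
        "Tpm": {"bTpm": 0.45, "aTpm": 0.55},
        "actin": {"sa-actin": 1.0},
    },
}

#: overall ion current per family relative to the most loaded one,
#: a modest order-of-magnitude spread across sarcomeric proteins
_FAMILY_LOADINGS: dict[str, float] = {
    "actin": 1.0,
    "Tpm": 0.7,
    "MLC1": 0.5,
    "MLC2": 0.45,
    "TnI": 0.25,
    "TnC": 0.15,
}


def mock_target_table() -> list[ProteoformSpec]:
    """Canonical (unmodified) target table over the mock sarcomeric library."""
    return [
        ProteoformSpec(id=p, protein_name=p, gene=v[0],
                       base_neutral_mass=v[1], phospho_sites_max=v[2])
        for p, v in MOCK_LIBRARY.items()
    ]


def fiber_fixture(
    kind: str,
    seed: int = 0,
    noise: NoiseModel | None = None,
    include_mlc2s_shift: bool | None = None,
) -> SyntheticRunConfig:
    """Fixture config for a slow, fast, or hybrid fiber archetype.

    Slow fibers weight ssTnI/MLC1V/MLC2S/ssTnC high, fast fibers weight
    fsTnI/MLC2F/MLC3F/fsTnC high, and the hybrid fiber mixes both; all carry
    mono-/bis-phospho satellites on the tropomyosins and regulatory light
    chains.  The hybrid fiber additionally carries the +29 Da MLC2S
    satellite species (unexplained-shift scenario) unless disabled.
    """
    if kind not in _FIBER_COMPOSITIONS:
        raise ValueError(
            f"unknown fixture kind {kind!r}; "
            f"choose from {sorted(_FIBER_COMPOSITIONS)}")
    if include_mlc2s_shift is None:
        include_mlc2s_shift = kind == "hybrid_fiber"
    if noise is None:
        noise = NoiseModel(intensity_cv=0.1, spurious_peak_rate=5.0)

    signals: list[ProteoformSignal] = []
    for family, split in _FIBER_COMPOSITIONS[kind].items():
        for protein, iso_frac in split.items():
            gene, mass, sites, fam, rt, _fast = MOCK_LIBRARY[protein]
            phospho = _PHOSPHO_SPLITS.get(protein, {0: 1.0})
            states: list[tuple[str, tuple, float, float]] = []
            for k, pf in phospho.items():
                mods = (("phospho", k),) if k else ()
                states.append((f"{protein}_{k}P", mods, mass, pf))
            if protein == "MLC2S" and include_mlc2s_shift:
                states = [(i, m, b, f * (1 - _MLC2S_SHIFT_FRACTION))
                          for i, m, b, f in states]
                states.append((f"{protein}_p29", (), mass + _MLC2S_SHIFT_DA,
                               _MLC2S_SHIFT_FRACTION))
            for pid, mods, base, pf in states:
                spec = ProteoformSpec(
                    id=pid, protein_name=protein, gene=gene,
                    base_neutral_mass=base, modifications=mods,
                    phospho_sites_max=sites)
                signals.append(ProteoformSignal(
                    spec=spec, abundance=iso_frac * pf,
                    rt_center=rt, rt_sigma=0.15, family=fam))
    return SyntheticRunConfig(
        proteoforms=signals,
        seed=seed,
        noise=noise,
        family_loadings=dict(_FAMILY_LOADINGS),
        quad_low_mass=None,
    )
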