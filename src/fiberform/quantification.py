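"""Per-fiber quantification: isoform ratios, proteoform abundances, P_total.

Three statistics per fiber:

* isoform relative abundance — the ratio of the EIC areas (AUC) of the
  isoforms in a protein family, using the top 5-7 most abundant charge
  states of each isoform as EIC windows;
* proteoform relative abundance — the ratio of a proteoform's peak
  intensity to the summed intensities of all proteoforms of that protein,
  from the deconvoluted averaged spectrum;
* total phosphorylation ``P_total = sum_j(k_j I_j) / sum_j(I_j)`` — mol
  phosphate per mol protein, the site-count-weighted intensity fraction of
  the phospho proteoforms.

:func:`fiber_report` orchestrates the full pipeline on one run: locate each
protein's elution, average the scans, deconvolute (isotopic route), fit,
assign, extract EICs, and quantify.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from .mass_model import (
    PROTON_MASS,
    ProteoformSpec,
    averagine_isotope_distribution,
    proteoform_mass,
)
from .spectra_io import Scan, SpectrumRun, average_spectra, auc, extract_eic, read_mzml
from .deconvolution import merge_charge_evidence, snap_monoisotopic
from .isotopic_fitting import fit_isotopic_pattern
from .proteoform_assignment import (
    Assignment,
    assign_peaks,
    proteoform_series,
)
from .synthetic_data import auto_charge_envelope

__all__ = [
    "AnalysisConfig",
    "QuantReport",
    "select_top_charge_states",
    "isoform_relative_abundance",
    "proteoform_relative_abundance",
    "total_phosphorylation",
    "fiber_report",
]


@dataclass
class AnalysisConfig:
    """Pipeline parameters for one fiber analysis.

    ``families`` groups protein names into slow/fast isoform families for
    the AUC ratio step; proteins not listed form singleton families.
    """

    families: dict[str, list[str]] = field(default_factory=dict)
    ppm_tol: float = 10.0
    max_unknown_shift: float = 100.0
    charge_range: tuple[int, int] = (5, 50)
    spacing_tol: float = 0.05
    min_cluster_score: float = 0.6
    eic_halfwidth: float = 0.2
    rt_window_halfwidth: float = 0.5
    cluster_tol: float = 0.01
    resolving_power: float = 60000.0
    n_top_charges: tuple[int, int] = (5, 7)
    pool_mod_states: bool = True
    use_integrated_cluster_intensity: bool = False
    detection_rel_threshold: float = 1e-3
    min_series_rel_intensity: float = 0.005
    rt_windows: dict[str, tuple[float, float]] = field(default_factory=dict)

    @classmethod
    def from_json(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            data = json.load(fh)
        cfg = cls(**data)
        cfg.charge_range = tuple(cfg.charge_range)
        cfg.n_top_charges = tuple(cfg.n_top_charges)
        cfg.rt_windows = {k: tuple(v) for k, v in cfg.rt_windows.items()}
        return cfg

    def family_of(self, protein: str) -> str:
        for fam, members in self.families.items():
            if protein in members:
                return fam
        return protein


@dataclass
class QuantReport:
    """Per-fiber result table plus provenance of the choices made."""

    fiber_id: str
    isoform_ratios: dict[str, dict[str, float]]
    pairwise_ratios: dict[str, float]
    proteoform_abundances: dict[str, dict[str, float]]
    total_phosphorylation: dict[str, float]
    detected: dict[str, bool]
    fits: dict[str, dict]
    provenance: dict

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def interference_intervals(
    masses: list[float],
    charge_range: tuple[int, int],
    halfwidth: float,
) -> list[tuple[float, float]]:
    """m/z intervals occupied by the charge-state clusters of given masses.

    Used to keep EIC windows of one isoform away from the predicted lines
    of co-eluting species: each interval covers one charge state's isotope
    cluster extent plus the EIC half-width on both sides.
    """
    out = []
    for m in masses:
        dist = averagine_isotope_distribution(m)
        extent = dist.neutral_masses[-1] - dist.neutral_masses[0]
        apex_mass = dist.most_abundant_mass
        for z in range(charge_range[0], charge_range[1] + 1):
            mz = (apex_mass + z * PROTON_MASS) / z
            half = extent / (2.0 * z) + halfwidth
            out.append((mz - half, mz + half))
    return out


def _conflicted(window: tuple[float, float],
                avoid: list[tuple[float, float]]) -> bool:
    lo, hi = window
    return any(lo < b and a < hi for a, b in avoid)


def select_top_charge_states(
    averaged: Scan,
    proteoform_mass_da: float,
    n_range: tuple[int, int] = (5, 7),
    charge_range: tuple[int, int] = (5, 50),
    eic_halfwidth: float = 0.2,
    match_tol: float = 0.05,
    avoid: list[tuple[float, float]] | None = None,
) -> list[tuple[int, tuple[float, float]]]:
    """Top 5-7 most abundant charge states of a proteoform, as EIC windows.

    Charge states are ranked by the apex intensity of the proteoform's
    isotope cluster at that charge in the averaged (non-deconvoluted)
    spectrum; each window is the most-abundant-isotopologue m/z plus/minus
    ``eic_halfwidth``.  Charges whose window would overlap an ``avoid``
    interval (predicted lines of co-eluting species) are skipped unless too
    few clean charges remain.
    """
    dist = averagine_isotope_distribution(proteoform_mass_da)
    apex_mass = dist.most_abundant_mass
    n_lo, n_hi = n_range
    found: list[tuple[float, int, float]] = []
    for z in range(charge_range[0], charge_range[1] + 1):
        mz = (apex_mass + z * PROTON_MASS) / z
        a = np.searchsorted(averaged.mz, mz - match_tol)
        b = np.searchsorted(averaged.mz, mz + match_tol)
        if b > a:
            found.append((float(averaged.intensity[a:b].max()), z, mz))
    if not found:
        raise ValueError(
            f"proteoform at {proteoform_mass_da:.1f} Da not detected in the "
            f"averaged spectrum")
    if avoid:
        clean = [f for f in found
                 if not _conflicted((f[2] - eic_halfwidth,
                                     f[2] + eic_halfwidth), avoid)]
        if len(clean) >= min(n_lo, len(found)):
            found = clean
        else:
            warnings.warn(
                f"fewer than {n_lo} interference-free charge states for "
                f"{proteoform_mass_da:.1f} Da; using the most intense ones")
    found.sort(key=lambda t: (-t[0], t[1]))
    n = min(n_hi, len(found))
    if n < n_lo:
        warnings.warn(
            f"only {n} charge states detected for {proteoform_mass_da:.1f} Da"
            f" (wanted at least {n_lo})")
    return [(z, (mz - eic_halfwidth, mz + eic_halfwidth))
            for _i, z, mz in found[:n]]


def charge_state_coverage(
    averaged: Scan,
    proteoform_mass_da: float,
    selected_charges: list[int],
    charge_range: tuple[int, int] = (5, 50),
    match_tol: float = 0.05,
) -> float:
    """Fraction of a proteoform's observed charge envelope carried by the
    selected charge states (apex-intensity weighted).

    Dividing an isoform's EIC AUC by this fraction makes AUC ratios
    comparable when interference filtering forces different isoforms onto
    differently sized charge-state subsets.
    """
    dist = averagine_isotope_distribution(proteoform_mass_da)
    apex_mass = dist.most_abundant_mass
    total = 0.0
    selected = 0.0
    for z in range(charge_range[0], charge_range[1] + 1):
        mz = (apex_mass + z * PROTON_MASS) / z
        a = np.searchsorted(averaged.mz, mz - match_tol)
        b = np.searchsorted(averaged.mz, mz + match_tol)
        if b > a:
            apex = float(averaged.intensity[a:b].max())
            total += apex
            if z in selected_charges:
                selected += apex
    return selected / total if total > 0 else 1.0


def isoform_relative_abundance(
    aucs: dict[str, float],
) -> dict[str, float]:
    """AUC fractions of the isoforms within one protein family."""
    total = sum(aucs.values())
    if total <= 0:
        raise ValueError("all isoform AUCs are zero")
    return {iso: a / total for iso, a in aucs.items()}


def proteoform_relative_abundance(
    series: list[Assignment],
) -> dict[str, float]:
    """Peak-intensity fractions of the proteoforms of one protein."""
    if not series:
        raise ValueError("empty proteoform series")
    total = sum(a.peak.intensity for a in series)
    if total <= 0:
        raise ValueError("zero total intensity in proteoform series")
    return {a.label: a.peak.intensity / total for a in series}


def total_phosphorylation(series: list[Assignment]) -> float:
    """P_total = sum(k_j I_j) / sum(I_j), mol Pi per mol protein."""
    if not series:
        raise ValueError("empty proteoform series")
    total = sum(a.peak.intensity for a in series)
    if total <= 0:
        raise ValueError("zero total intensity in proteoform series")
    return sum(a.phospho_count * a.peak.intensity for a in series) / total


def _locate_elution(
    run: SpectrumRun,
    target: ProteoformSpec,
    config: AnalysisConfig,
) -> tuple[tuple[float, float], float]:
    """Coarse EIC over the theoretical top charges; returns (window, apex)."""
    if target.protein_name in config.rt_windows:
        lo, hi = config.rt_windows[target.protein_name]
        return (lo, hi), np.nan
    mass = proteoform_mass(target)
    dist = averagine_isotope_distribution(mass)
    zc, _zs = auto_charge_envelope(mass)
    windows = []
    for z in range(max(config.charge_range[0], zc - 2),
                   min(config.charge_range[1], zc + 2) + 1):
        mz = (dist.most_abundant_mass + z * PROTON_MASS) / z
        windows.append((mz - config.eic_halfwidth, mz + config.eic_halfwidth))
    trace = extract_eic(run, windows, label=target.protein_name)
    apex = trace.apex_rt
    hw = config.rt_window_halfwidth
    return (apex - hw, apex + hw), float(trace.intensity.max())


def fiber_report(
    run: SpectrumRun | str,
    targets: list[ProteoformSpec],
    config: AnalysisConfig | None = None,
    fiber_id: str = "fiber",
) -> QuantReport:
    """Run the full MS1 pipeline on one fiber and report all statistics.

    ``run`` may be a :class:`SpectrumRun` or a path to an mzML file.
    Undetected proteins are reported with zero abundance and a detection
    flag rather than dropped, so cross-fiber tables stay rectangular.
    """
    if isinstance(run, (str, bytes)) or hasattr(run, "__fspath__"):
        run = read_mzml(run)
    if config is None:
        config = AnalysisConfig()
    targets = sorted(targets, key=lambda t: t.id)

    proteoform_abundances: dict[str, dict[str, float]] = {}
    p_total: dict[str, float] = {}
    detected: dict[str, bool] = {}
    fits: dict[str, dict] = {}
    aucs_by_protein: dict[str, float] = {}
    provenance: dict = {
        "ppm_tol": config.ppm_tol,
        "charge_range": list(config.charge_range),
        "eic_halfwidth": config.eic_halfwidth,
        "rt_windows": {},
        "charge_states": {},
        "intensity_mode": ("integrated" if config.use_integrated_cluster_intensity
                           else "apex"),
    }

    apex_heights: dict[str, float] = {}
    windows_by_protein: dict[str, tuple[float, float]] = {}
    for t in targets:
        try:
            window, apex_height = _locate_elution(run, t, config)
        except Exception as exc:  # pragma: no cover - propagated with context
            raise RuntimeError(
                f"elution location failed for {t.protein_name} "
                f"({fiber_id})") from exc
        windows_by_protein[t.protein_name] = window
        apex_heights[t.protein_name] = apex_height
    height_max = max(v for v in apex_heights.values() if np.isfinite(v))

    for t in targets:
        protein = t.protein_name
        window = windows_by_protein[protein]
        provenance["rt_windows"][protein] = list(window)
        detected[protein] = bool(
            apex_heights[protein] >= config.detection_rel_threshold * height_max
            or not np.isfinite(apex_heights[protein]))
        if not detected[protein]:
            proteoform_abundances[protein] = {}
            p_total[protein] = 0.0
            aucs_by_protein[protein] = 0.0
            continue

        averaged = average_spectra(run, window, cluster_tol=config.cluster_tol)
        clusters, _rem = snap_monoisotopic(
            averaged,
            charge_range=config.charge_range,
            spacing_tol=config.spacing_tol,
            min_score=config.min_cluster_score,
        )
        decon = merge_charge_evidence(
            clusters, resolving_power=config.resolving_power)
        if config.use_integrated_cluster_intensity:
            for peak in decon.peaks:
                peak.intensity = sum(
                    float(c.intensities.sum()) for c in clusters
                    if abs(c.monoisotopic_mass - peak.neutral_mass)
                    / peak.neutral_mass * 1e6 <= 10.0)
        assignments = assign_peaks(
            decon, targets,
            ppm_tol=config.ppm_tol,
            max_unknown_shift=config.max_unknown_shift)
        series = proteoform_series(assignments, protein, targets)
        if series:
            floor = config.min_series_rel_intensity * max(
                a.peak.intensity for a in series)
            series = [a for a in series if a.peak.intensity >= floor]
        # a protein counts as detected only when at least one of its
        # expected (matched) proteoforms is present -- a series of nothing
        # but unexplained shifts is interference, not detection
        if not any(a.status == "matched" for a in series):
            series = []
        if not series:
            detected[protein] = False
            proteoform_abundances[protein] = {}
            p_total[protein] = 0.0
            aucs_by_protein[protein] = 0.0
            continue
        proteoform_abundances[protein] = proteoform_relative_abundance(series)
        p_total[protein] = total_phosphorylation(series)

        matched_plain = [a for a in series
                         if a.status == "matched" and not a.mods]
        matched = [a for a in series if a.status == "matched"]
        base = (matched_plain or matched or series)
        base = max(base, key=lambda a: a.peak.intensity)
        fit = fit_isotopic_pattern(
            _cluster_profile(clusters, base.peak.neutral_mass),
            candidate_mass=proteoform_mass(t))
        fits[protein] = {
            "calculated_mass_da": fit.calculated_mass,
            "experimental_mass_da": fit.experimental_mass,
            "ppm": fit.ppm,
            "fit_score_pct": fit.fit_score,
        }

        # EIC windows: top charge states of the base proteoform, optionally
        # pooling the m/z positions of every assigned modification state;
        # windows stay clear of the predicted lines of co-eluting targets
        lo_w, hi_w = window
        others = [u for u in targets
                  if u.protein_name != protein
                  and windows_by_protein[u.protein_name][0] < hi_w
                  and lo_w < windows_by_protein[u.protein_name][1]]
        avoid = interference_intervals(
            [m for u in others
             for m, _mods in _phospho_series_masses(u)],
            config.charge_range, config.eic_halfwidth)
        quant_masses = ([a.peak.neutral_mass for a in series]
                        if config.pool_mod_states
                        else [base.peak.neutral_mass])
        charge_sel = select_top_charge_states(
            averaged, base.peak.neutral_mass,
            n_range=config.n_top_charges,
            charge_range=config.charge_range,
            eic_halfwidth=config.eic_halfwidth,
            avoid=avoid)
        provenance["charge_states"][protein] = [z for z, _w in charge_sel]
        windows = []
        for z, _w in charge_sel:
            for m in quant_masses:
                dist_apex = (averagine_isotope_distribution(m).most_abundant_mass
                             + z * PROTON_MASS) / z
                w = (dist_apex - config.eic_halfwidth,
                     dist_apex + config.eic_halfwidth)
                if not _conflicted(w, avoid):
                    windows.append(w)
        with warnings.catch_warnings():
            # pooled modification-state windows legitimately overlap at
            # high charge; merging is the intended behaviour here
            warnings.filterwarnings("ignore", message="overlapping m/z")
            trace = extract_eic(run, windows, label=protein)
        coverage = charge_state_coverage(
            averaged, base.peak.neutral_mass,
            [z for z, _w in charge_sel], config.charge_range)
        aucs_by_protein[protein] = auc(trace, rt_bounds=window) / coverage

    # family-level isoform ratios from the per-protein AUCs
    families: dict[str, dict[str, float]] = {}
    for t in targets:
        fam = config.family_of(t.protein_name)
        families.setdefault(fam, {})[t.protein_name] = aucs_by_protein.get(
            t.protein_name, 0.0)
    isoform_ratios = {}
    for fam, aucs in families.items():
        if sum(aucs.values()) > 0:
            isoform_ratios[fam] = isoform_relative_abundance(aucs)
        else:
            isoform_ratios[fam] = {p: 0.0 for p in aucs}
    pairwise = {}
    for fam, aucs in families.items():
        for a in sorted(aucs):
            for b in sorted(aucs):
                if a != b and aucs[b] > 0:
                    pairwise[f"{a}/{b}"] = aucs[a] / aucs[b]

    return QuantReport(
        fiber_id=fiber_id,
        isoform_ratios=isoform_ratios,
        pairwise_ratios=pairwise,
        proteoform_abundances=proteoform_abundances,
        total_phosphorylation=p_total,
        detected=detected,
        fits=fits,
        provenance=provenance,
    )


def _phospho_series_masses(target: ProteoformSpec):
    """(mass, mods) of the target's phosphorylation states."""
    base = proteoform_mass(target)
    from .mass_model import MOD_DELTAS

    return [(base + k * MOD_DELTAS["phospho"], (("phospho", k),) if k else ())
            for k in range(target.phospho_sites_max + 1)]


def _cluster_profile(clusters, mono_mass: float, tol_ppm: float = 10.0):
    """Neutral-mass isotope profile of the best cluster near a mass."""
    near = [c for c in clusters
            if abs(c.monoisotopic_mass - mono_mass) / mono_mass * 1e6 <= tol_ppm]
    best = max(near, key=lambda c: c.apex_intensity)
    masses = best.inferred_charge * (best.mzs - PROTON_MASS)
    return masses, best.intensities
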