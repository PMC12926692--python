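"""Charge deconvolution: multiply-charged m/z spectra to neutral masses.

Two complementary routes:

* :func:`snap_monoisotopic` — isotopically resolved route.  Peaks are
  grouped into clusters of near-uniform spacing, the charge follows from
  the spacing (``z = round(1.00235 / spacing)``), the cluster is scored
  against the averagine pattern for its implied mass, and the monoisotopic
  mass is read off the matched isotopologue indices.
  :func:`merge_charge_evidence` then combines clusters that agree across
  charge states into single neutral-mass peaks.

* :func:`envelope_deconvolute` — iterative nonnegative (Richardson-Lucy
  style) deconvolution of the whole spectrum onto a zero-charge mass grid,
  with an optional entropy penalty.  This follows the operational contract
  of the maximum-entropy tools used on QTOF intact-protein data without
  claiming bit-compatibility with any vendor implementation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .mass_model import (
    AVG_ISOTOPE_SPACING,
    PROTON_MASS,
    averagine_isotope_distribution,
)
from .spectra_io import CENTROID, Scan

__all__ = [
    "IsotopicCluster",
    "DeconPeak",
    "DeconvolutedSpectrum",
    "snap_monoisotopic",
    "merge_charge_evidence",
    "envelope_deconvolute",
]

_FWHM = 2.3548200450309493


@dataclass
class IsotopicCluster:
    """An isotopologue cluster at one charge state."""

    mzs: np.ndarray
    intensities: np.ndarray
    inferred_charge: int
    monoisotopic_mass: float
    cluster_score: float  # cosine vs averagine pattern, in [0, 1]

    @property
    def apex_intensity(self) -> float:
        return float(self.intensities.max())

    @property
    def n_isotopologues(self) -> int:
        return int(self.mzs.size)


@dataclass
class DeconPeak:
    neutral_mass: float
    intensity: float
    supporting_charges: tuple[int, ...]
    n_isotopologues_matched: int
    score: float | None = None


@dataclass
class DeconvolutedSpectrum:
    """Zero-charge neutral-mass peak list with supporting evidence."""

    peaks: list[DeconPeak]
    method: str  # "envelope" | "isotopic"
    resolving_power_setting: float

    def __post_init__(self) -> None:
        self.peaks = sorted(self.peaks, key=lambda p: p.neutral_mass)

    @property
    def masses(self) -> np.ndarray:
        return np.array([p.neutral_mass for p in self.peaks])

    @property
    def intensities(self) -> np.ndarray:
        return np.array([p.intensity for p in self.peaks])


# ---------------------------------------------------------------------------
# SNAP-style isotopic route

_AVERAGINE_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _averagine_pattern(mass: float) -> tuple[np.ndarray, np.ndarray]:
    """(offsets-from-mono, probabilities) for ~mass, cached on a 200 Da grid.

    Offsets are measured from the true monoisotopic mass, which for large
    proteins may itself lie below the truncation threshold and be absent
    from the kept peaks.
    """
    key = max(3, int(round(mass / 200.0)))
    if key not in _AVERAGINE_CACHE:
        dist = averagine_isotope_distribution(key * 200.0, truncate_at=1e-5)
        _AVERAGINE_CACHE[key] = (
            dist.neutral_masses - key * 200.0,
            dist.probabilities,
        )
    return _AVERAGINE_CACHE[key]


def _walk_chain(
    mz: np.ndarray,
    used: np.ndarray,
    seed: int,
    spacing: float,
    tol_abs: float,
) -> list[int]:
    """Greedy bidirectional chain of peaks at near-uniform spacing."""
    chain = [seed]
    for direction in (1, -1):
        pos = mz[seed]
        while True:
            target = pos + direction * spacing
            j = np.searchsorted(mz, target)
            best = -1
            best_err = tol_abs
            for k in (j - 1, j):
                if 0 <= k < mz.size and not used[k] and k not in chain:
                    err = abs(mz[k] - target)
                    if err < best_err:
                        best, best_err = k, err
            if best < 0:
                break
            chain.append(best)
            pos = mz[best]
    chain.sort()
    return chain


def _score_chain(
    mz: np.ndarray,
    inten: np.ndarray,
    z: int,
) -> tuple[float, float, int]:
    """Fit a charge-z m/z chain against averagine (see _fit_mass_series)."""
    return _fit_mass_series(z * (mz - PROTON_MASS), inten)


def _fit_mass_series(
    masses: np.ndarray,
    inten: np.ndarray,
) -> tuple[float, float, int]:
    """Fit a neutral-mass isotopologue series against averagine.

    Aligns the observed intensities to the theoretical pattern by the best
    integer lag, which pins down which member is which isotopologue.
    Returns (cosine score, monoisotopic mass, n matched isotopologues).
    """
    apex = int(np.argmax(inten))
    offsets, probs = _averagine_pattern(masses[apex])
    theo_apex = int(np.argmax(probs))
    # isotopologue index of each chain member relative to the chain apex
    rel = np.round((masses - masses[apex]) / AVG_ISOTOPE_SPACING).astype(int)
    best = (-1.0, 0.0, 0)
    for lag in range(-6, 7):
        idx = rel + theo_apex + lag
        inside = (idx >= 0) & (idx < probs.size)
        if not np.any(inside):
            continue
        theo_vec = np.zeros(probs.size + np.count_nonzero(~inside))
        obs_vec = np.zeros_like(theo_vec)
        theo_vec[: probs.size] = probs
        obs_vec[idx[inside]] = inten[inside]
        extra = np.nonzero(~inside)[0]
        obs_vec[probs.size : probs.size + extra.size] = inten[extra]
        denom = np.linalg.norm(theo_vec) * np.linalg.norm(obs_vec)
        score = float(theo_vec @ obs_vec / denom) if denom > 0 else 0.0
        if score > best[0]:
            w = inten[inside]
            mono = float(np.average(
                masses[inside] - offsets[idx[inside]], weights=w))
            best = (score, mono, int(np.count_nonzero(inside)))
    return best


def snap_monoisotopic(
    spectrum: Scan,
    charge_range: tuple[int, int] = (5, 50),
    spacing_tol: float = 0.05,
    min_score: float = 0.6,
    min_peaks: int = 3,
    min_rel_intensity: float = 1e-3,
) -> tuple[list[IsotopicCluster], list[int]]:
    """Spacing-based charge inference plus averagine-fit validation.

    Works on a centroided spectrum.  Returns the accepted clusters together
    with the indices of peaks that could not be assigned to any cluster (the
    remainder list).  Candidate charges for a seed peak are read from the
    gaps to its neighbours; the final charge is re-derived from the median
    observed spacing, which disambiguates adjacent charges.  Ties between
    charges explaining the same seed break toward the higher cluster score,
    then the lower charge.
    """
    if spectrum.mode != CENTROID:
        raise ValueError("snap_monoisotopic requires a centroided spectrum")
    mz = spectrum.mz
    inten = spectrum.intensity
    clusters: list[IsotopicCluster] = []
    if mz.size == 0:
        return clusters, []
    z_min, z_max = charge_range
    used = np.zeros(mz.size, dtype=bool)
    threshold = min_rel_intensity * inten.max()
    seeds = np.argsort(inten, kind="stable")[::-1]
    seeds = seeds[inten[seeds] >= threshold]

    for seed in seeds:
        if used[seed]:
            continue
        # candidate charges from observed gaps to neighbouring peaks
        cand: list[int] = []
        for z in range(z_max, z_min - 1, -1):
            s = AVG_ISOTOPE_SPACING / z
            tol_abs = spacing_tol * s
            hit = False
            for target in (mz[seed] - s, mz[seed] + s):
                j = np.searchsorted(mz, target)
                for k in (j - 1, j):
                    if 0 <= k < mz.size and abs(mz[k] - target) <= tol_abs:
                        hit = True
            if hit:
                cand.append(z)
        best: tuple[float, int, list[int], float, int] | None = None
        tried: set[int] = set()
        for z in cand:
            if z in tried:
                continue
            s = AVG_ISOTOPE_SPACING / z
            chain = _walk_chain(mz, used, seed, s, spacing_tol * s)
            if len(chain) < min_peaks:
                continue
            diffs = np.diff(mz[chain])
            med = float(np.median(diffs))
            z_ref = int(round(AVG_ISOTOPE_SPACING / med))
            if z_ref != z:
                if z_min <= z_ref <= z_max and z_ref not in cand:
                    cand.append(z_ref)
                continue
            tried.add(z)
            expected = AVG_ISOTOPE_SPACING / z
            if abs(med - expected) / expected > spacing_tol:
                continue
            score, mono, n_match = _score_chain(mz[chain], inten[chain], z)
            if score < min_score:
                continue
            key = (score, -z)
            if best is None or key > (best[0], -best[1]):
                best = (score, z, chain, mono, n_match)
        if best is not None:
            score, z, chain, mono, _n = best
            used[chain] = True
            clusters.append(IsotopicCluster(
                mzs=mz[chain].copy(),
                intensities=inten[chain].copy(),
                inferred_charge=z,
                monoisotopic_mass=mono,
                cluster_score=score,
            ))
    remainder = np.nonzero(~used)[0].tolist()
    clusters.sort(key=lambda c: (c.monoisotopic_mass, c.inferred_charge))
    return clusters, remainder


def merge_charge_evidence(
    clusters: list[IsotopicCluster],
    merge_tol_ppm: float = 10.0,
    resolving_power: float = 60000.0,
) -> DeconvolutedSpectrum:
    """Combine per-charge clusters agreeing in monoisotopic mass.

    Clusters within ``merge_tol_ppm`` of a growing intensity-weighted mean
    merge into one peak whose intensity is the sum of the cluster apex
    intensities.
    """
    peaks: list[DeconPeak] = []
    pending = sorted(clusters, key=lambda c: c.monoisotopic_mass)
    group: list[IsotopicCluster] = []

    def flush() -> None:
        if not group:
            return
        w = np.array([c.apex_intensity for c in group])
        m = np.array([c.monoisotopic_mass for c in group])
        peaks.append(DeconPeak(
            neutral_mass=float(np.average(m, weights=w)),
            intensity=float(w.sum()),
            supporting_charges=tuple(sorted({c.inferred_charge for c in group})),
            n_isotopologues_matched=max(c.n_isotopologues for c in group),
            score=float(max(c.cluster_score for c in group)),
        ))

    mean = 0.0
    wsum = 0.0
    for c in pending:
        if group and abs(c.monoisotopic_mass - mean) / mean * 1e6 > merge_tol_ppm:
            flush()
            group, mean, wsum = [], 0.0, 0.0
        group.append(c)
        w = c.apex_intensity
        mean = (mean * wsum + c.monoisotopic_mass * w) / (wsum + w)
        wsum += w
    flush()
    return DeconvolutedSpectrum(peaks=peaks, method="isotopic",
                                resolving_power_setting=resolving_power)


# ---------------------------------------------------------------------------
# iterative nonnegative envelope deconvolution


def render_charged_spectrum(
    grid_M: np.ndarray,
    h: np.ndarray,
    charges: np.ndarray,
    grid_mz: np.ndarray,
    sigma_bins: float,
) -> np.ndarray:
    """Render a mass-domain function through every charge onto an m/z grid.

    This is the forward model of :func:`envelope_deconvolute`: linear
    resampling of ``h`` along ``M = z (m/z - proton)`` with the charge as
    the Jacobian, then a Gaussian blur of ``sigma_bins`` grid steps.
    """
    acc = np.zeros_like(grid_mz)
    for z in charges:
        Mq = z * (grid_mz - PROTON_MASS)
        acc += z * np.interp(Mq, grid_M, h, left=0.0, right=0.0)
    return gaussian_filter1d(acc, sigma_bins, mode="constant")


def envelope_deconvolute(
    spectrum: Scan,
    mass_range: tuple[float, float],
    charge_range: tuple[int, int] = (5, 50),
    resolving_power: float = 60000.0,
    max_iter: int = 500,
    tol: float = 1e-4,
    rel_peak_threshold: float = 1e-3,
    entropy_weight: float = 0.0,
) -> tuple[DeconvolutedSpectrum, np.ndarray, np.ndarray]:
    """Richardson-Lucy style deconvolution onto a zero-charge mass grid.

    The forward model renders a nonnegative mass-domain function ``h(M)``
    (grid step ``M/(2R)``) through every charge in ``charge_range`` and a
    Gaussian peak-shape of FWHM ``m/z / R``, and iterates the multiplicative
    update until the relative residual change drops below ``tol``.  Local
    maxima of ``h`` are chained into isotopologue series (~1.00235 Da apart)
    and reported as one peak per series (monoisotopic mass, summed
    intensity).  Returns ``(peaks, mass_grid, h)``.
    """
    m_lo, m_hi = mass_range
    if not m_lo < m_hi:
        raise ValueError("mass_range must satisfy lo < hi")
    z_lo, z_hi = charge_range
    if z_lo > z_hi or z_lo < 1:
        raise ValueError("invalid charge_range")
    empty = DeconvolutedSpectrum(peaks=[], method="envelope",
                                 resolving_power_setting=resolving_power)
    if spectrum.mz.size == 0 or spectrum.intensity.sum() == 0:
        return empty, np.empty(0), np.empty(0)

    charges = np.arange(z_lo, z_hi + 1)
    m_mid = 0.5 * (m_lo + m_hi)
    dM = m_mid / (2.0 * resolving_power)
    grid_M = np.arange(m_lo, m_hi + dM, dM)

    mz_lo = (m_lo + z_hi * PROTON_MASS) / z_hi
    mz_hi = (m_hi + z_lo * PROTON_MASS) / z_lo
    mz_lo = max(mz_lo, spectrum.mz.min() - 1.0)
    mz_hi = min(mz_hi, spectrum.mz.max() + 1.0)
    if mz_lo >= mz_hi:
        return empty, grid_M, np.zeros_like(grid_M)
    sigma_mz = (0.5 * (mz_lo + mz_hi)) / resolving_power / _FWHM
    d_mz = sigma_mz / 3.0
    grid_mz = np.arange(mz_lo, mz_hi + d_mz, d_mz)
    sigma_bins = sigma_mz / d_mz

    y = np.zeros_like(grid_mz)
    sel = (spectrum.mz >= mz_lo) & (spectrum.mz <= mz_hi)
    if spectrum.mode == CENTROID:
        idx = np.clip(np.round((spectrum.mz[sel] - mz_lo) / d_mz).astype(int),
                      0, grid_mz.size - 1)
        np.add.at(y, idx, spectrum.intensity[sel])
        y = gaussian_filter1d(y, sigma_bins, mode="constant")
    else:
        y = np.interp(grid_mz, spectrum.mz[sel], spectrum.intensity[sel],
                      left=0.0, right=0.0)
    if y.sum() == 0:
        return empty, grid_M, np.zeros_like(grid_M)

    mz_of_M = [(grid_M + z * PROTON_MASS) / z for z in charges]

    def forward(h: np.ndarray) -> np.ndarray:
        return render_charged_spectrum(grid_M, h, charges, grid_mz,
                                       sigma_bins)

    def adjoint(r: np.ndarray) -> np.ndarray:
        rs = gaussian_filter1d(r, sigma_bins, mode="constant")
        acc = np.zeros_like(grid_M)
        for z, mzq in zip(charges, mz_of_M):
            acc += z * np.interp(mzq, grid_mz, rs, left=0.0, right=0.0)
        return acc

    h = np.full_like(grid_M, y.sum() / (grid_M.size * charges.size))
    norm = adjoint(np.ones_like(grid_mz))
    norm[norm <= 0] = norm[norm > 0].min() if np.any(norm > 0) else 1.0
    eps = 1e-12 * y.max()
    prev_res = np.inf
    for _ in range(max_iter):
        y_hat = forward(h)
        res = float(np.linalg.norm(y - y_hat) / np.linalg.norm(y))
        if abs(prev_res - res) < tol * max(res, 1e-30):
            break
        prev_res = res
        h = h * (adjoint(y / (y_hat + eps)) / norm)
        if entropy_weight > 0.0:
            mean_h = h.mean()
            if mean_h > 0:
                h = h * np.exp(-entropy_weight
                               * np.log(np.maximum(h / mean_h, 1e-12)) * 1e-3)

    peaks = _pick_envelope_peaks(grid_M, h, rel_peak_threshold)
    # supporting charges: fraction of the rendered contribution per charge
    out: list[DeconPeak] = []
    for member_masses, members, intensity in peaks:
        score, mono, _n = _fit_mass_series(
            member_masses, np.array([h[m] for m in members]))
        lo_m = grid_M[members[0]] - 0.5
        hi_m = grid_M[members[-1]] + 0.5
        mask = (grid_M >= lo_m) & (grid_M <= hi_m)
        h_local = np.where(mask, h, 0.0)
        contrib = np.array([
            z * np.interp(z * (grid_mz - PROTON_MASS), grid_M, h_local,
                          left=0.0, right=0.0).sum()
            for z in charges
        ])
        total = contrib.sum()
        support = (tuple(int(z) for z, c in zip(charges, contrib)
                         if total > 0 and c > 0.05 * total)
                   or (int(charges[np.argmax(contrib)]),))
        out.append(DeconPeak(
            neutral_mass=mono,
            intensity=intensity,
            supporting_charges=support,
            n_isotopologues_matched=len(members),
            score=score,
        ))
    return (
        DeconvolutedSpectrum(peaks=out, method="envelope",
                             resolving_power_setting=resolving_power),
        grid_M,
        h,
    )


def _pick_envelope_peaks(
    grid_M: np.ndarray,
    h: np.ndarray,
    rel_threshold: float,
) -> list[tuple[np.ndarray, list[int], float]]:
    """Local maxima of h, chained into isotopologue series.

    Returns (refined member masses, member maxima indices, summed intensity)
    per series; maxima positions are parabolically refined.
    """
    if h.size < 3 or h.max() <= 0:
        return []
    thr = rel_threshold * h.max()
    is_max = (h[1:-1] >= h[:-2]) & (h[1:-1] > h[2:]) & (h[1:-1] >= thr)
    maxima = np.nonzero(is_max)[0] + 1
    if maxima.size == 0:
        return []
    refined = []
    dM = grid_M[1] - grid_M[0]
    for i in maxima:
        a, b, c = h[i - 1], h[i], h[i + 1]
        denom = a - 2 * b + c
        delta = 0.5 * (a - c) / denom if denom != 0 else 0.0
        refined.append(grid_M[i] + delta * dM)
    refined = np.array(refined)
    # chain consecutive maxima ~one neutron apart into one series
    series: list[list[int]] = [[0]]
    for k in range(1, maxima.size):
        gap = refined[k] - refined[series[-1][-1]]
        if abs(gap - AVG_ISOTOPE_SPACING) < 0.35:
            series[-1].append(k)
        else:
            series.append([k])
    out = []
    for s in series:
        members = [int(maxima[k]) for k in s]
        intensity = float(sum(h[m] for m in members))
        out.append((refined[np.array(s)], members, intensity))
    return out
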