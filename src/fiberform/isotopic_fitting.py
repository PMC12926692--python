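"""Validation of deconvoluted masses by theoretical isotope-pattern fits.

For each candidate mass the averagine distribution is aligned to the
observed cluster by a single mass offset (grid search plus parabolic
refinement) and a free scale; the fit score is the cosine similarity
between the aligned theoretical and observed intensity vectors, expressed
in percent, so a perfect match scores 100 regardless of absolute intensity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mass_model import averagine_isotope_distribution, ppm_error

__all__ = ["FitResult", "fit_isotopic_pattern"]


@dataclass
class FitResult:
    """Outcome of one isotope-pattern fit (the per-proteoform report row)."""

    calculated_mass: float
    experimental_mass: float
    ppm: float
    fit_score: float  # percent, in [0, 100]
    scale: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.fit_score <= 100.0 + 1e-9):
            raise ValueError("fit_score must lie in [0, 100]")


def _score_at_offset(
    obs_mass: np.ndarray,
    obs_int: np.ndarray,
    theo_mass: np.ndarray,
    theo_prob: np.ndarray,
    offset: float,
    match_tol: float,
) -> tuple[float, float]:
    """(cosine, scale) with the theoretical pattern shifted by offset."""
    shifted = theo_mass + offset
    idx = np.searchsorted(obs_mass, shifted)
    theo_vec = theo_prob
    obs_vec = np.zeros_like(theo_prob)
    matched_obs: set[int] = set()
    for k, m in enumerate(shifted):
        best = -1
        best_err = match_tol
        for j in (idx[k] - 1, idx[k]):
            if 0 <= j < obs_mass.size and j not in matched_obs:
                err = abs(obs_mass[j] - m)
                if err < best_err:
                    best, best_err = j, err
        if best >= 0:
            obs_vec[k] = obs_int[best]
            matched_obs.add(best)
    # observed peaks with no theoretical partner penalize the fit
    extra = [i for i in range(obs_mass.size) if i not in matched_obs
             and theo_mass[0] + offset - match_tol
             <= obs_mass[i] <= theo_mass[-1] + offset + match_tol]
    if extra:
        obs_vec = np.concatenate([obs_vec, obs_int[extra]])
        theo_vec = np.concatenate([theo_prob, np.zeros(len(extra))])
    denom = np.linalg.norm(theo_vec) * np.linalg.norm(obs_vec)
    if denom == 0:
        return 0.0, 0.0
    cos = float(theo_vec @ obs_vec / denom)
    tt = float(theo_vec @ theo_vec)
    scale = float(theo_vec @ obs_vec / tt) if tt > 0 else 0.0
    return cos, scale


def fit_isotopic_pattern(
    observed: tuple[np.ndarray, np.ndarray],
    candidate_mass: float,
    offset_range: float = 0.5,
    coarse_step: float = 0.001,
    match_tol: float = 0.05,
    truncate_at: float = 1e-4,
) -> FitResult:
    """Fit the averagine pattern for ``candidate_mass`` to an observed cluster.

    ``observed`` is a (neutral mass, intensity) pair of arrays (ascending
    masses, at least three points).  The offset search runs on a coarse grid
    of ``coarse_step`` Da within +/-``offset_range`` Da, then refines the
    best offset parabolically.  The experimental mass is the offset-corrected
    monoisotopic mass; the ppm error compares it with the candidate.
    """
    obs_mass = np.asarray(observed[0], dtype=float)
    obs_int = np.asarray(observed[1], dtype=float)
    if obs_mass.size < 3:
        raise ValueError("isotopic fit needs at least 3 observed points")
    if candidate_mass <= 0:
        raise ValueError("candidate_mass must be positive")
    order = np.argsort(obs_mass)
    obs_mass, obs_int = obs_mass[order], obs_int[order]

    theo = averagine_isotope_distribution(candidate_mass, truncate_at)
    theo_mass = theo.neutral_masses
    theo_prob = theo.probabilities

    offsets = np.arange(-offset_range, offset_range + coarse_step, coarse_step)
    scores = np.empty(offsets.size)
    for i, off in enumerate(offsets):
        scores[i], _ = _score_at_offset(
            obs_mass, obs_int, theo_mass, theo_prob, off, match_tol)
    best_off = float(offsets[int(np.argmax(scores))])
    # center the offset on the matched peaks: the cosine is flat within the
    # match tolerance, so the residual mean is what pins the mass down
    best_off = _center_offset(obs_mass, obs_int, theo_mass, theo_prob,
                              best_off, match_tol)
    score, scale = _score_at_offset(
        obs_mass, obs_int, theo_mass, theo_prob, best_off, match_tol)
    experimental = candidate_mass + best_off
    return FitResult(
        calculated_mass=candidate_mass,
        experimental_mass=experimental,
        ppm=ppm_error(experimental, candidate_mass),
        fit_score=max(0.0, min(100.0, round(100.0 * score, 9))),
        scale=scale,
    )


def _center_offset(
    obs_mass: np.ndarray,
    obs_int: np.ndarray,
    theo_mass: np.ndarray,
    theo_prob: np.ndarray,
    offset: float,
    match_tol: float,
) -> float:
    """Shift the offset by the intensity-weighted mean matched residual."""
    shifted = theo_mass + offset
    idx = np.searchsorted(obs_mass, shifted)
    residuals = []
    for k, m in enumerate(shifted):
        best_err = None
        for j in (idx[k] - 1, idx[k]):
            if 0 <= j < obs_mass.size:
                err = obs_mass[j] - m
                if best_err is None or abs(err) < abs(best_err):
                    best_err = err
        if best_err is not None and abs(best_err) < match_tol:
            residuals.append(best_err)
    if not residuals:
        return offset
    return offset + float(np.mean(residuals))
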