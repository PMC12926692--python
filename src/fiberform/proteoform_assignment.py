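"""Match deconvoluted neutral masses to a proteoform target table.

Each deconvoluted peak is tested against every target's modification
series (phospho up to the target's site count, limited oxidation and
acetylation); the best match inside the ppm tolerance wins.  A peak near a
target series but outside the ppm tolerance is reported as *shifted* with
its residual mass delta — this is how unexplained species such as a +29 Da
satellite surface instead of being silently absorbed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

from .mass_model import MOD_DELTAS, ProteoformSpec, ppm_error, proteoform_mass
from .deconvolution import DeconPeak, DeconvolutedSpectrum

__all__ = [
    "Assignment",
    "assign_peaks",
    "proteoform_series",
    "enumerate_candidates",
]

MATCHED = "matched"
SHIFTED = "shifted"
UNASSIGNED = "unassigned"


@dataclass
class Assignment:
    """One peak's verdict: matched to a proteoform, shifted, or unassigned."""

    peak: DeconPeak
    proteoform_id: str | None
    protein_name: str | None
    mods: tuple[tuple[str, int], ...]
    ppm: float | None
    status: str
    shift_da: float | None = None

    @property
    def phospho_count(self) -> int:
        return sum(c for n, c in self.mods if n == "phospho")

    @property
    def label(self) -> str:
        if self.proteoform_id is None:
            return UNASSIGNED
        tags = [f"{c}x{n}" if c > 1 else n for n, c in self.mods if c]
        if self.status == SHIFTED:
            tags.append(f"{self.shift_da:+.1f}Da")
        return self.proteoform_id + (("+" + "+".join(tags)) if tags else "")


def enumerate_candidates(
    target: ProteoformSpec,
    max_oxidation: int = 2,
    max_acetyl: int = 1,
) -> list[tuple[float, tuple[tuple[str, int], ...]]]:
    """All (mass, mods) combinations allowed for one target."""
    out = []
    base = proteoform_mass(target)
    for n_p, n_ox, n_ac in itertools.product(
            range(target.phospho_sites_max + 1),
            range(max_oxidation + 1),
            range(max_acetyl + 1)):
        mods = tuple((n, c) for n, c in (
            ("phospho", n_p), ("oxidation", n_ox), ("acetyl", n_ac)) if c)
        mass = base + sum(MOD_DELTAS[n] * c for n, c in mods)
        out.append((mass, mods))
    return out


def assign_peaks(
    decon: DeconvolutedSpectrum,
    targets: list[ProteoformSpec],
    ppm_tol: float = 10.0,
    max_unknown_shift: float = 100.0,
    max_oxidation: int = 2,
    max_acetyl: int = 1,
) -> list[Assignment]:
    """Assign every deconvoluted peak to at most one proteoform.

    Match ranking: smallest absolute ppm error within ``ppm_tol``; ties
    break toward fewer total modifications, then lexicographic target id.
    A peak that matches nothing but lies within ``max_unknown_shift`` Da of
    some target's phosphorylation series gets status ``shifted`` with the
    residual delta (vs the nearest phospho state) rounded to 0.1 Da, so a
    +29 Da satellite of an unmodified target reports a 29.0 Da shift;
    everything else is ``unassigned``.
    """
    if not targets:
        raise ValueError("targets must be non-empty")
    if ppm_tol <= 0:
        raise ValueError("ppm_tol must be positive")
    candidates = []
    shift_refs = []
    for t in sorted(targets, key=lambda t: t.id):
        for mass, mods in enumerate_candidates(t, max_oxidation, max_acetyl):
            candidates.append((mass, t, mods))
            if all(n == "phospho" for n, _c in mods):
                shift_refs.append((mass, t, mods))

    out: list[Assignment] = []
    for peak in decon.peaks:
        best: tuple[float, int, str] | None = None
        best_entry = None
        near: tuple[float, object, tuple] | None = None
        for mass, t, mods in candidates:
            err = ppm_error(peak.neutral_mass, mass)
            n_mods = sum(c for _n, c in mods)
            key = (abs(err), n_mods, t.id)
            if abs(err) <= ppm_tol:
                if best is None or key < best:
                    best = key
                    best_entry = (t, mods, err)
        for mass, t, mods in shift_refs:
            delta = peak.neutral_mass - mass
            if abs(delta) <= max_unknown_shift:
                if near is None or abs(delta) < abs(near[0]):
                    near = (delta, t, mods)
        if best_entry is not None:
            t, mods, err = best_entry
            out.append(Assignment(
                peak=peak, proteoform_id=t.id, protein_name=t.protein_name,
                mods=mods, ppm=err, status=MATCHED))
        elif near is not None:
            delta, t, mods = near
            out.append(Assignment(
                peak=peak, proteoform_id=t.id, protein_name=t.protein_name,
                mods=mods, ppm=None, status=SHIFTED,
                shift_da=round(delta, 1)))
        else:
            out.append(Assignment(
                peak=peak, proteoform_id=None, protein_name=None,
                mods=(), ppm=None, status=UNASSIGNED))
    return out


def proteoform_series(
    assignments: list[Assignment],
    protein_name: str,
    targets: list[ProteoformSpec] | None = None,
) -> list[Assignment]:
    """Matched and shifted assignments of one protein, ordered by mass.

    An empty list is a valid outcome (protein not detected); asking for a
    protein absent from the target table raises.
    """
    if targets is not None and all(
            t.protein_name != protein_name for t in targets):
        raise KeyError(f"protein {protein_name!r} not in target table")
    series = [a for a in assignments
              if a.protein_name == protein_name and a.status != UNASSIGNED]
    series.sort(key=lambda a: a.peak.neutral_mass)
    return series
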