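"""Mass, charge, and isotope arithmetic shared by every pipeline stage.

All neutral masses in this package are monoisotopic daltons unless a name
says otherwise.  Theoretical isotope patterns are built from the averagine
model: a protein of given mass is approximated by a scaled "average amino
acid" elemental composition, and the aggregated (unit-neutron-resolved)
isotopologue distribution is computed by exact elemental convolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from pyteomics.mass import nist_mass

__all__ = [
    "PROTON_MASS",
    "AVERAGINE_MONOMER_MASS",
    "AVERAGINE_COMPOSITION",
    "AVG_ISOTOPE_SPACING",
    "MOD_DELTAS",
    "ProteoformSpec",
    "IsotopeDistribution",
    "mz_from_mass",
    "mass_from_mz",
    "ppm_error",
    "averagine_composition",
    "averagine_isotope_distribution",
    "most_abundant_offset",
    "proteoform_mass",
    "read_target_table",
    "write_target_table",
]

PROTON_MASS: float = 1.007276466
AVERAGINE_MONOMER_MASS: float = 111.1254
#: fractional atoms of each element per 111.1254 Da averagine monomer (Senko)
AVERAGINE_COMPOSITION: dict[str, float] = {
    "C": 4.9384,
    "H": 7.7583,
    "N": 1.3577,
    "O": 1.4773,
    "S": 0.0417,
}
#: mean spacing between adjacent aggregated isotopologues of a peptide/protein
AVG_ISOTOPE_SPACING: float = 1.00235

#: monoisotopic mass deltas of the modifications the pipeline knows about
MOD_DELTAS: dict[str, float] = {
    "phospho": 79.96633,
    "oxidation": 15.99491,
    "acetyl": 42.01057,
}


def mz_from_mass(neutral_mass: float, charge: int) -> float:
    """m/z of the [M + zH]^z+ ion of a neutral monoisotopic mass."""
    if neutral_mass <= 0:
        raise ValueError(f"neutral_mass must be positive, got {neutral_mass}")
    if charge < 1:
        raise ValueError(f"charge must be a positive integer, got {charge}")
    return (neutral_mass + charge * PROTON_MASS) / charge


def mass_from_mz(mz: float, charge: int) -> float:
    """Neutral monoisotopic mass from the m/z of an [M + zH]^z+ ion."""
    if charge < 1:
        raise ValueError(f"charge must be a positive integer, got {charge}")
    mass = charge * (mz - PROTON_MASS)
    if mass <= 0:
        raise ValueError(f"m/z {mz} at charge {charge} implies non-positive mass")
    return mass


def ppm_error(experimental: float, calculated: float) -> float:
    """Signed relative mass error in parts per million."""
    if calculated <= 0:
        raise ValueError("calculated mass must be positive")
    return (experimental - calculated) / calculated * 1e6


@dataclass(frozen=True)
class ProteoformSpec:
    """A named intact species: a protein isoform plus a modification state.

    Parameters
    ----------
    id : str
        Unique short identifier within a target table (e.g. ``"aTpm_1P"``).
    protein_name : str
        Isoform name as used in the field (e.g. ``"MLC2S"``).
    gene : str
        Gene symbol (e.g. ``"MYL2"``).
    base_neutral_mass : float
        Monoisotopic mass of the unmodified chain, Da.
    modifications : tuple of (str, int)
        Modification name/count pairs; names must exist in :data:`MOD_DELTAS`.
    phospho_sites_max : int
        Number of known phosphorylatable sites on this protein.
    """

    id: str
    protein_name: str
    gene: str
    base_neutral_mass: float
    modifications: tuple[tuple[str, int], ...] = ()
    phospho_sites_max: int = 0

    def __post_init__(self) -> None:
        if self.base_neutral_mass <= 0:
            raise ValueError(f"{self.id}: base_neutral_mass must be positive")
        if self.phospho_sites_max < 0:
            raise ValueError(f"{self.id}: phospho_sites_max must be >= 0")
        object.__setattr__(self, "modifications", tuple(
            (str(n), int(c)) for n, c in self.modifications))
        if self.phospho_count > self.phospho_sites_max:
            raise ValueError(
                f"{self.id}: phospho count {self.phospho_count} exceeds "
                f"phospho_sites_max {self.phospho_sites_max}")

    @property
    def phospho_count(self) -> int:
        return sum(c for n, c in self.modifications if n == "phospho")


def proteoform_mass(spec: ProteoformSpec) -> float:
    """Monoisotopic neutral mass of a proteoform: base mass plus PTM deltas."""
    mass = spec.base_neutral_mass
    for name, count in spec.modifications:
        try:
            mass += count * MOD_DELTAS[name]
        except KeyError:
            raise KeyError(
                f"unknown modification {name!r} on {spec.id}; "
                f"known: {sorted(MOD_DELTAS)}") from None
    return mass


@dataclass
class IsotopeDistribution:
    """Aggregated isotopologue distribution of a neutral species.

    ``neutral_masses`` are centroid masses of the unit-neutron-aggregated
    isotopologue peaks, ascending; ``probabilities`` sum to one.
    """

    neutral_masses: np.ndarray
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        self.neutral_masses = np.asarray(self.neutral_masses, dtype=float)
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if self.neutral_masses.shape != self.probabilities.shape:
            raise ValueError("masses and probabilities must have equal length")
        if np.any(np.diff(self.neutral_masses) <= 0):
            raise ValueError("neutral_masses must be strictly ascending")
        if abs(self.probabilities.sum() - 1.0) > 1e-9:
            raise ValueError("probabilities must sum to 1")

    @property
    def monoisotopic_mass(self) -> float:
        return float(self.neutral_masses[0])

    @property
    def most_abundant_index(self) -> int:
        return int(np.argmax(self.probabilities))

    @property
    def most_abundant_mass(self) -> float:
        return float(self.neutral_masses[self.most_abundant_index])


def averagine_composition(neutral_mass: float) -> dict[str, int]:
    """Integer elemental composition approximating a protein of given mass.

    C/N/O/S counts scale with mass; the hydrogen count absorbs the rounding
    residual so the model monoisotopic mass lands as close to the target as
    an integer formula allows.
    """
    n_monomers = neutral_mass / AVERAGINE_MONOMER_MASS
    comp = {
        el: int(round(n_monomers * frac))
        for el, frac in AVERAGINE_COMPOSITION.items()
        if el != "H"
    }
    h_mono = nist_mass["H"][0][0]
    heavy = sum(nist_mass[el][0][0] * n for el, n in comp.items())
    comp["H"] = max(0, int(round((neutral_mass - heavy) / h_mono)))
    return comp


def _element_neutron_distribution(element: str) -> tuple[np.ndarray, np.ndarray]:
    """Single-atom (probability, mass-delta) arrays indexed by extra neutrons."""
    isotopes = {k: v for k, v in nist_mass[element].items()
                if k != 0 and v[1] > 0}
    mono = min(isotopes)
    size = max(round(k - mono) for k in isotopes) + 1
    p = np.zeros(size)
    s = np.zeros(size)  # probability-weighted mass delta
    mono_mass = isotopes[mono][0]
    for k, (mass, abundance) in isotopes.items():
        idx = round(k - mono)
        p[idx] += abundance
        s[idx] += abundance * (mass - mono_mass)
    return p, s


def _convolve_ps(a: tuple[np.ndarray, np.ndarray],
                 b: tuple[np.ndarray, np.ndarray],
                 tail: float) -> tuple[np.ndarray, np.ndarray]:
    """Convolve two (probability, weighted-mass) aggregated distributions."""
    pa, sa = a
    pb, sb = b
    p = np.convolve(pa, pb)
    s = np.convolve(sa, pb) + np.convolve(pa, sb)
    # trim the far tail to keep repeated squaring cheap; renormalisation of
    # the final result absorbs the clipped probability mass
    keep = np.nonzero(p > tail * p.max())[0]
    return p[: keep[-1] + 1], s[: keep[-1] + 1]


def _atom_power(dist: tuple[np.ndarray, np.ndarray], n: int,
                tail: float) -> tuple[np.ndarray, np.ndarray]:
    """n-fold self-convolution by binary exponentiation."""
    result: tuple[np.ndarray, np.ndarray] | None = None
    base = dist
    while n > 0:
        if n & 1:
            result = base if result is None else _convolve_ps(result, base, tail)
        n >>= 1
        if n:
            base = _convolve_ps(base, base, tail)
    if result is None:
        return np.array([1.0]), np.array([0.0])
    return result


def averagine_isotope_distribution(
    neutral_mass: float,
    truncate_at: float = 1e-4,
) -> IsotopeDistribution:
    """Theoretical aggregated isotope pattern for a protein of given mass.

    The elemental composition comes from :func:`averagine_composition`; the
    aggregated distribution is computed by exact convolution of per-element
    isotope distributions (binary exponentiation over atom counts), then
    anchored so the monoisotopic peak sits exactly at ``neutral_mass``.
    Peaks below ``truncate_at`` times the apex are dropped and the remainder
    renormalised.
    """
    if not (500.0 <= neutral_mass <= 500_000.0):
        raise ValueError(
            f"neutral_mass {neutral_mass} outside supported range [500, 5e5] Da")
    if not (0.0 < truncate_at < 1.0):
        raise ValueError("truncate_at must be in (0, 1)")
    comp = averagine_composition(neutral_mass)
    tail = min(truncate_at, 1e-6) * 1e-3
    acc: tuple[np.ndarray, np.ndarray] | None = None
    for el, n in comp.items():
        if n == 0:
            continue
        d = _atom_power(_element_neutron_distribution(el), n, tail)
        acc = d if acc is None else _convolve_ps(acc, d, tail)
    assert acc is not None
    p, s = acc
    with np.errstate(invalid="ignore", divide="ignore"):
        delta = np.where(p > 0, s / np.maximum(p, 1e-300), 0.0)
    keep = p >= truncate_at * p.max()
    # keep a contiguous block around the apex so spacings stay ~1 neutron
    idx = np.nonzero(keep)[0]
    lo, hi = idx[0], idx[-1]
    p, delta = p[lo : hi + 1], delta[lo : hi + 1]
    # delta[k] is the centroid offset of the k-th isotopologue from the
    # composition's monoisotopic peak, so anchoring is a plain shift
    masses = neutral_mass + delta
    return IsotopeDistribution(masses, p / p.sum())


def most_abundant_offset(neutral_mass: float) -> float:
    """Mass offset (Da) of the most abundant isotopologue above monoisotopic."""
    dist = averagine_isotope_distribution(neutral_mass)
    return dist.most_abundant_mass - dist.monoisotopic_mass


# ---------------------------------------------------------------------------
# target-table I/O


def _format_mods(mods: tuple[tuple[str, int], ...]) -> str:
    return ";".join(f"{n}:{c}" for n, c in mods)


def _parse_mods(text: str) -> tuple[tuple[str, int], ...]:
    text = (text or "").strip()
    if not text:
        return ()
    out = []
    for item in text.split(";"):
        name, _, count = item.partition(":")
        out.append((name.strip(), int(count) if count else 1))
    return tuple(out)


def read_target_table(path) -> list[ProteoformSpec]:
    """Read a proteoform target table (TSV) into :class:`ProteoformSpec` rows.

    Columns: ``id, protein_name, gene, base_neutral_mass_da, modifications,
    phospho_sites_max``; modifications use a semicolon list ``name:count``.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    specs = []
    for row in df.itertuples(index=False):
        specs.append(ProteoformSpec(
            id=row.id,
            protein_name=row.protein_name,
            gene=row.gene,
            base_neutral_mass=float(row.base_neutral_mass_da),
            modifications=_parse_mods(row.modifications),
            phospho_sites_max=int(row.phospho_sites_max or 0),
        ))
    ids = [s.id for s in specs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate proteoform ids in target table")
    return specs


def write_target_table(specs: list[ProteoformSpec], path) -> None:
    import pandas as pd

    pd.DataFrame({
        "id": [s.id for s in specs],
        "protein_name": [s.protein_name for s in specs],
        "gene": [s.gene for s in specs],
        "base_neutral_mass_da": [s.base_neutral_mass for s in specs],
        "modifications": [_format_mods(s.modifications) for s in specs],
        "phospho_sites_max": [s.phospho_sites_max for s in specs],
    }).to_csv(path, sep="\t", index=False)
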