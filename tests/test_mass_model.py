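"""Mass/charge arithmetic and averagine isotope distributions.

The isotope-distribution implementation (binary-exponentiation elemental
convolution) is checked against an independent brute-force oracle that
enumerates isotope-count vectors per element with multinomial probabilities.
"""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from pyteomics.mass import nist_mass
from scipy.stats import multinomial

from fiberform.mass_model import (
    MOD_DELTAS,
    ProteoformSpec,
    averagine_composition,
    averagine_isotope_distribution,
    mass_from_mz,
    mz_from_mass,
    ppm_error,
    proteoform_mass,
    read_target_table,
    write_target_table,
)


# ---------------------------------------------------------------------------
# brute-force oracle: multinomial enumeration per element, aggregated by
# total extra-neutron count


def _element_isotopes(element):
    iso = sorted((k, v) for k, v in nist_mass[element].items()
                 if k != 0 and v[1] > 0)
    mono_mass = iso[0][1][0]
    return [(round(k - iso[0][0]), mass - mono_mass, ab)
            for k, (mass, ab) in iso], mono_mass


def brute_force_distribution(comp, tail=1e-12):
    """Aggregated isotopologue distribution by explicit enumeration."""
    agg = {0: (1.0, 0.0)}  # neutron index -> (prob, prob-weighted mass delta)
    for element, n in comp.items():
        isotopes, _mono = _element_isotopes(element)
        shifts = [s for s, _d, _a in isotopes]
        deltas = {s: d for s, d, _a in isotopes}
        probs = [a for _s, _d, a in isotopes]
        probs = [p / sum(probs) for p in probs]
        elem_agg = {}
        for counts in _partitions(n, len(isotopes)):
            p = multinomial.pmf(counts, n, probs)
            if p < tail:
                continue
            k = sum(c * s for c, s in zip(counts, shifts))
            d = sum(c * deltas[s] for c, s in zip(counts, shifts))
            prev = elem_agg.get(k, (0.0, 0.0))
            elem_agg[k] = (prev[0] + p, prev[1] + p * d)
        new = {}
        for k1, (p1, d1) in agg.items():
            for k2, (p2, d2) in elem_agg.items():
                prev = new.get(k1 + k2, (0.0, 0.0))
                new[k1 + k2] = (prev[0] + p1 * p2,
                                prev[1] + p1 * d2 + p2 * d1)
        agg = new
    ks = sorted(agg)
    p = np.array([agg[k][0] for k in ks])
    with np.errstate(invalid="ignore"):
        d = np.array([agg[k][1] / agg[k][0] if agg[k][0] > 0 else 0.0
                      for k in ks])
    return np.array(ks), p, d


def _partitions(n, bins):
    if bins == 1:
        yield (n,)
        return
    for first in range(n + 1):
        for rest in _partitions(n - first, bins - 1):
            yield (first,) + rest


# ---------------------------------------------------------------------------


class TestChargeArithmetic:
    def test_known_values(self):
        assert mz_from_mass(20000.0, 20) == pytest.approx(1001.007276466)
        assert mz_from_mass(1000.0, 1) == pytest.approx(1001.007276466)

    @given(st.floats(min_value=500, max_value=5e5),
           st.integers(min_value=1, max_value=80))
    def test_round_trip(self, mass, z):
        assert mass_from_mz(mz_from_mass(mass, z), z) == pytest.approx(
            mass, rel=1e-9)

    @given(st.floats(min_value=500, max_value=5e5),
           st.integers(min_value=1, max_value=79))
    def test_strictly_decreasing_in_charge(self, mass, z):
        assert mz_from_mass(mass, z + 1) < mz_from_mass(mass, z)

    @pytest.mark.parametrize("mass,z", [(-1.0, 5), (0.0, 5), (100.0, 0),
                                        (100.0, -2)])
    def test_domain_errors(self, mass, z):
        with pytest.raises(ValueError):
            mz_from_mass(mass, z)


class TestPpm:
    def test_signed(self):
        assert ppm_error(1000.001, 1000.0) == pytest.approx(1.0)
        assert ppm_error(999.999, 1000.0) == pytest.approx(-1.0)
        assert ppm_error(1234.5, 1234.5) == 0.0

    def test_requires_positive_calculated(self):
        with pytest.raises(ValueError):
            ppm_error(1.0, 0.0)


class TestProteoformMass:
    def test_deltas(self):
        base = ProteoformSpec(id="p", protein_name="P", gene="G",
                              base_neutral_mass=10000.0)
        assert proteoform_mass(base) == 10000.0
        phospho = ProteoformSpec(id="p1", protein_name="P", gene="G",
                                 base_neutral_mass=10000.0,
                                 modifications=(("phospho", 1),),
                                 phospho_sites_max=1)
        assert proteoform_mass(phospho) == pytest.approx(10079.96633)
        multi = ProteoformSpec(id="p2", protein_name="P", gene="G",
                               base_neutral_mass=10000.0,
                               modifications=(("phospho", 2),
                                              ("oxidation", 1)),
                               phospho_sites_max=2)
        assert proteoform_mass(multi) == pytest.approx(10175.92757)

    def test_unknown_mod_named_in_error(self):
        spec = ProteoformSpec(id="p", protein_name="P", gene="G",
                              base_neutral_mass=1000.0,
                              modifications=(("glyco", 1),))
        with pytest.raises(KeyError, match="glyco"):
            proteoform_mass(spec)

    def test_phospho_cap_enforced(self):
        with pytest.raises(ValueError, match="phospho"):
            ProteoformSpec(id="p", protein_name="P", gene="G",
                           base_neutral_mass=1000.0,
                           modifications=(("phospho", 3),),
                           phospho_sites_max=2)


class TestAveragineDistribution:
    def test_monoisotopic_most_abundant_at_1kda(self):
        dist = averagine_isotope_distribution(1000.0)
        assert dist.most_abundant_index == 0

    @pytest.mark.parametrize("mass", [800.0, 2500.0, 5000.0])
    def test_matches_brute_force_oracle(self, mass):
        comp = averagine_composition(mass)
        ks, p_oracle, _d = brute_force_distribution(comp)
        dist = averagine_isotope_distribution(mass, truncate_at=1e-9)
        n = min(p_oracle.size, dist.probabilities.size)
        # oracle probabilities are unnormalized only by the enumeration tail
        assert np.allclose(dist.probabilities[:n]
                           * dist.probabilities[:n].sum() ** 0,
                           p_oracle[:n] / p_oracle.sum(), atol=1e-6)

    def test_matches_pyteomics_isotopologue_enumeration(self):
        """Secondary cross-check against pyteomics' own enumerator."""
        from pyteomics.mass import Composition, calculate_mass, isotopologues

        mass = 800.0
        comp = averagine_composition(mass)
        base = Composition(comp)
        mono = calculate_mass(composition=base)
        agg = {}
        for c, ab in isotopologues(composition=base, report_abundance=True,
                                   overall_threshold=1e-10):
            k = round(calculate_mass(composition=c) - mono)
            agg[k] = agg.get(k, 0.0) + ab
        # coarse check on raw abundances: pyteomics prunes isotopes rarer
        # than its default isotope_threshold (2H, 17O), so agreement is at
        # the per-mille level; the tight oracle is the multinomial one above
        dist = averagine_isotope_distribution(mass, truncate_at=1e-9)
        for k in sorted(agg)[:6]:
            assert dist.probabilities[k] == pytest.approx(agg[k], abs=7e-3)

    def test_apex_and_offset_match_oracle_at_20kda(self):
        comp = averagine_composition(20000.0)
        ks, p_oracle, d_oracle = brute_force_distribution(comp, tail=1e-10)
        dist = averagine_isotope_distribution(20000.0, truncate_at=1e-7)
        apex_oracle = int(ks[np.argmax(p_oracle)])
        # absolute isotopologue index of the implementation's apex
        offset_impl = dist.most_abundant_mass - 20000.0
        apex_impl = round(offset_impl / 1.00235)
        assert apex_impl == apex_oracle
        assert abs(offset_impl - d_oracle[apex_oracle]) < 0.001

    @pytest.mark.parametrize("mass", [900.0, 12000.0, 45000.0, 90000.0])
    def test_normalized_spaced_unimodal(self, mass):
        dist = averagine_isotope_distribution(mass)
        assert dist.probabilities.sum() == pytest.approx(1.0, abs=1e-9)
        spacing = np.diff(dist.neutral_masses)
        assert np.all((spacing >= 1.0) & (spacing <= 1.007))
        p = dist.probabilities
        if p.size >= 5:
            sm = np.convolve(p, np.ones(3) / 3, mode="valid")
            maxima = np.sum((sm[1:-1] > sm[:-2]) & (sm[1:-1] > sm[2:]))
            assert maxima <= 1

    def test_mass_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            averagine_isotope_distribution(100.0)
        with pytest.raises(ValueError):
            averagine_isotope_distribution(1e6)


class TestTargetTable:
    def test_round_trip(self, tmp_path):
        specs = [
            ProteoformSpec(id="a", protein_name="A", gene="GA",
                           base_neutral_mass=18000.0, phospho_sites_max=2),
            ProteoformSpec(id="a_1P", protein_name="A", gene="GA",
                           base_neutral_mass=18000.0,
                           modifications=(("phospho", 1),),
                           phospho_sites_max=2),
        ]
        path = tmp_path / "targets.tsv"
        write_target_table(specs, path)
        back = read_target_table(path)
        assert back == specs

    def test_duplicate_ids_rejected(self, tmp_path):
        specs = [ProteoformSpec(id="a", protein_name="A", gene="G",
                                base_neutral_mass=1000.0)] * 2
        path = tmp_path / "targets.tsv"
        write_target_table(specs, path)
        with pytest.raises(ValueError, match="duplicate"):
            read_target_table(path)
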