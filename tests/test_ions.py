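"""Negative-ion m/z, isotope envelopes, target tables, CID series."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rnashotgun.chem import (
    ElementalComposition,
    ISOTOPE_ABUNDANCE,
    MONOISOTOPIC_MASS,
    PROTON_MASS,
    WATER,
    apply_isotope_label,
    default_registry,
)
from rnashotgun.digestion import Fragment, parse_annotated_sequence
from rnashotgun.ions import (
    ISOTOPOLOGUE_SPACING,
    build_target_table,
    isotope_envelope,
    mz_negative,
    predict_cid_series,
)

REGISTRY = default_registry()


class TestMzNegative:
    def test_labelled_ho5u_nucleoside_prints_261(self, registry):
        """Singly ¹⁸O-labelled 5-hydroxyuridine, deprotonated: m/z 261 nominal."""
        comp = apply_isotope_label(registry.residue_composition("ho5U"), "O", 18, 1)
        mz = mz_negative(comp.mass(), 1)
        assert mz == pytest.approx(261.0614, abs=1e-3)
        assert round(mz) == 261

    def test_ug_fragment_charge_states(self, registry):
        frag = Fragment("x", 1, 2, ("U", "G"), "OH", "linear_phosphate")
        from rnashotgun.digestion import fragment_mass

        mass = fragment_mass(frag, registry)
        assert mz_negative(mass, 1) == pytest.approx(668.0760, abs=5e-5)
        assert mz_negative(mass, 2) == pytest.approx(333.5344, abs=5e-5)

    def test_invalid_charge_rejected(self):
        with pytest.raises(ValueError):
            mz_negative(500.0, 0)

    @settings(max_examples=50, deadline=None)
    @given(
        st.floats(min_value=100, max_value=5000),
        st.integers(min_value=1, max_value=6),
        st.integers(min_value=0, max_value=3),
    )
    def test_charge_consistency(self, mass, z, k):
        """z·(m/z) + z·proton recovers the neutral isotopologue mass."""
        mz = mz_negative(mass, z, k)
        assert z * mz + z * PROTON_MASS == pytest.approx(
            mass + k * ISOTOPOLOGUE_SPACING, abs=1e-6
        )

    @settings(max_examples=30, deadline=None)
    @given(st.floats(min_value=100, max_value=5000))
    def test_mz_strictly_decreases_with_charge(self, mass):
        values = [mz_negative(mass, z) for z in range(1, 6)]
        assert all(a > b for a, b in zip(values, values[1:]))


def brute_force_envelope(comp: ElementalComposition, k_max: int) -> np.ndarray:
    """Enumerate all isotopologue placements atom by atom (small compositions)."""
    dist = np.zeros(k_max + 1)
    dist[0] = 1.0
    atoms = []
    for element, n in comp.natural_counts().items():
        atoms.extend([element] * n)
    probs = np.zeros(k_max + 1)
    choices = [ISOTOPE_ABUNDANCE[a] for a in atoms]
    for assignment in itertools.product(*choices):
        shift = sum(s for s, _ in assignment)
        if shift <= k_max:
            p = 1.0
            for _, frac in assignment:
                p *= frac
            probs[shift] += p
    return probs / probs[0]


class TestEnvelope:
    def test_single_carbon_ratio(self):
        env = isotope_envelope(ElementalComposition.from_formula("C"), 1)
        assert env[1] == pytest.approx(0.0107 / 0.9893, abs=1e-4)

    def test_ho5u_m1_ratio(self, registry):
        env = isotope_envelope(registry.residue_composition("ho5U"), 2)
        assert env[1] == pytest.approx(0.11, abs=0.01)

    def test_kmax_zero(self, registry):
        env = isotope_envelope(registry.residue_composition("U"), 0)
        assert env.tolist() == [1.0]

    @pytest.mark.parametrize("formula", ["C3H5", "C2N2O2", "H2O2S", "C4O3"])
    def test_convolution_matches_brute_force(self, formula):
        comp = ElementalComposition.from_formula(formula)
        assert sum(comp.natural_counts().values()) <= 12
        env = isotope_envelope(comp, 3)
        oracle = brute_force_envelope(comp, 3)
        np.testing.assert_allclose(env, oracle, rtol=1e-9)

    def test_labelled_atoms_do_not_spread(self, registry):
        comp = registry.residue_composition("ho5U")
        labelled = apply_isotope_label(comp, "O", 18, 7)  # all oxygens fixed
        env_l = isotope_envelope(labelled, 2)
        # remaining spread comes from C, H, N only
        reduced = ElementalComposition.from_formula("C9H12N2")
        np.testing.assert_allclose(env_l, isotope_envelope(reduced, 2), rtol=1e-12)


class TestTargetTable:
    def test_counting_states_times_charges(self, registry, demo_trna):
        specs = build_target_table(
            [demo_trna], {demo_trna.id: ["U", "cmo5U"]}, charges=(1, 2), registry=registry
        )
        assert len(specs) == 4
        assert {(s.state, s.z) for s in specs} == {
            ("U", 1), ("U", 2), ("cmo5U", 1), ("cmo5U", 2),
        }
        # all specs of the locus share coordinates
        assert len({(s.start, s.end) for s in specs}) == 1

    def test_ho5u_state_differs_by_oxygen(self, registry, demo_trna):
        specs = build_target_table(
            [demo_trna], {demo_trna.id: ["U", "ho5U"]}, charges=(1,), registry=registry
        )
        by_state = {s.state: s.mz for s in specs}
        assert by_state["ho5U"] - by_state["U"] == pytest.approx(15.9949, abs=1e-4)

    def test_methyl_ester_splits_by_half_ch2_at_z2(self, registry, demo_trna):
        specs = build_target_table(
            [demo_trna], {demo_trna.id: ["cmo5U", "mcmo5U"]}, charges=(2,), registry=registry
        )
        mz = {s.state: s.mz for s in specs}
        neutral = {s.state: s.neutral_mass for s in specs}
        assert (neutral["mcmo5U"] - neutral["cmo5U"]) / 2 == pytest.approx(7.0078, abs=1e-4)
        # reported m/z values are rounded to 4 decimals individually
        assert mz["mcmo5U"] - mz["cmo5U"] == pytest.approx(7.0078, abs=2e-4)

    def test_incompatible_state_rejected(self, registry, demo_trna):
        with pytest.raises(ValueError, match="incompatible"):
            build_target_table(
                [demo_trna], {demo_trna.id: ["m7G"]}, charges=(1,), registry=registry
            )

    def test_missing_anticodon_rejected(self, registry):
        seq = parse_annotated_sequence("x", "AUGCG", [], registry)
        with pytest.raises(ValueError, match="anticodon"):
            build_target_table([seq], {"x": ["U"]}, charges=(1,), registry=registry)


class TestCID:
    def test_ug_c1_y1_reference_values(self, registry):
        frag = Fragment("x", 1, 2, ("U", "G"), "OH", "linear_phosphate")
        ions = {(i.series, i.index): i.neutral_mass for i in predict_cid_series(frag, registry)}
        assert ions[("c", 1)] == pytest.approx(324.0359, abs=5e-5)
        assert ions[("y", 1)] == pytest.approx(363.0580, abs=5e-5)
        assert ions[("c", 1)] + ions[("y", 1)] == pytest.approx(687.0939, abs=1e-4)

    def test_single_residue_yields_empty_with_warning(self, registry):
        frag = Fragment("x", 1, 1, ("G",), "OH", "OH")
        with pytest.warns(UserWarning):
            assert predict_cid_series(frag, registry) == []

    def test_w_ion_is_y_plus_phosphate(self, registry):
        frag = Fragment("x", 1, 3, ("A", "U", "G"), "OH", "linear_phosphate")
        ions = {(i.series, i.index): i.neutral_mass for i in predict_cid_series(frag, registry)}
        from rnashotgun.chem import HPO3

        for idx in (1, 2):
            assert ions[("w", idx)] - ions[("y", idx)] == pytest.approx(HPO3.mass(), abs=1e-6)

    def test_complementarity_on_random_fragments(self, registry):
        rng = np.random.default_rng(42)
        from rnashotgun.digestion import fragment_mass
        from conftest import random_sequence

        for _ in range(30):
            residues = tuple(random_sequence(rng, registry, int(rng.integers(2, 12))))
            frag = Fragment("r", 1, len(residues), residues, "OH", "linear_phosphate")
            parent = fragment_mass(frag, registry)
            ions = predict_cid_series(frag, registry, series=("c", "y"))
            c = {i.index: i.neutral_mass for i in ions if i.series == "c"}
            y = {i.index: i.neutral_mass for i in ions if i.series == "y"}
            n = len(residues)
            for i in range(1, n):
                assert c[i] + y[n - i] == pytest.approx(parent + WATER.mass(), abs=1e-6)
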