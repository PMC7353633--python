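"""Adulteration design enumeration and mass-balance predictions."""

import numpy as np
import pandas as pd
import pytest

import milkscreen as ms
from milkscreen.adulteration import (
    AdulterationRecipe,
    TARGET_PROTEIN,
    TARGET_TS,
    apply_recipe,
    combined_dose,
    enumerate_design,
    registry_specs,
)
from milkscreen.schema import FEATURES


@pytest.fixture(scope="module")
def specs(registry):
    return registry_specs(registry)


@pytest.fixture(scope="module")
def pool_b(pools):
    p = next(p for p in pools if p.pool_id == "B")
    return pd.Series({v: p.means[v] for v in FEATURES})


class TestEnumeration:
    def test_full_registry_yields_288_plus_51(self, registry):
        recipes = enumerate_design(["A", "B", "C"], registry)
        assert sum(r.mode == "single" for r in recipes) == 288
        assert sum(r.mode == "combined" for r in recipes) == 51

    def test_empty_registry_yields_nothing(self, registry):
        assert enumerate_design(["A", "B", "C"], registry.iloc[:0]) == []

    def test_water_only_registry_gives_12_single_recipes(self, registry):
        water_only = registry[registry["category"] == "water"]
        recipes = enumerate_design(["A", "B", "C"], water_only)
        assert len(recipes) == 12 and all(r.mode == "single" for r in recipes)

    def test_deterministic_ordering(self, registry):
        a = enumerate_design(["A", "B", "C"], registry)
        b = enumerate_design(["A", "B", "C"], registry)
        assert a == b

    def test_unknown_category_rejected(self, registry):
        bad = registry.copy()
        bad.loc["URE", "category"] = "mystery"
        with pytest.raises(ValueError, match="category"):
            enumerate_design(["A"], bad)


class TestApplyRecipe:
    def test_zero_water_is_identity(self, pool_b, specs):
        r = AdulterationRecipe(pool_id="B", code="WATER", mode="single", level=1, added_mass=0.0)
        out = apply_recipe(pool_b, r, specs["WATER"])
        np.testing.assert_allclose(out[list(FEATURES)], pool_b[list(FEATURES)], atol=1e-12)

    def test_40g_water_dilutes_protein_by_mass_balance(self, pool_b, specs):
        r = AdulterationRecipe(pool_id="B", code="WATER", mode="single", level=4, added_mass=40.0)
        out = apply_recipe(pool_b, r, specs["WATER"])
        assert out["protein"] == pytest.approx(3.44 * 100 / 140, abs=1e-9)

    @pytest.mark.parametrize("code", ["URE", "MLM", "AS", "AC", "DIC", "WPI", "SMP"])
    def test_apparent_protein_strictly_increases_with_level(self, pool_b, specs, code):
        doses = [0.5, 1.0, 2.0, 4.0]
        proteins = [
            apply_recipe(
                pool_b,
                AdulterationRecipe("B", code, "single", level=i + 1, added_mass=d),
                specs[code],
            )["protein"]
            for i, d in enumerate(doses)
        ]
        assert all(b > a for a, b in zip(proteins, proteins[1:]))

    def test_total_solids_nondecreasing_for_non_water_categories(self, pool_b, specs):
        for code, spec in specs.items():
            if spec.category == "water":
                continue
            prev = pool_b["ts"]
            for dose in (0.5, 1.0, 2.0):
                out = apply_recipe(
                    pool_b,
                    AdulterationRecipe("B", code, "single", level=1, added_mass=dose),
                    spec,
                )
                assert out["ts"] >= prev - 1e-12, code
                prev = out["ts"]

    def test_fpd_strictly_decreases_with_water_fraction(self, pool_b, specs):
        fpds = [
            apply_recipe(
                pool_b,
                AdulterationRecipe("B", "WATER", "single", level=1, added_mass=w),
                specs["WATER"],
            )["fpd"]
            for w in (0.0, 10.0, 20.0, 30.0, 40.0)
        ]
        assert all(b < a for a, b in zip(fpds, fpds[1:]))

    def test_negative_added_mass_rejected(self, pool_b, specs):
        with pytest.raises(ValueError):
            AdulterationRecipe("B", "URE", "single", level=1, added_mass=-1.0)


class TestMassBalanceOracle:
    """apply_recipe against an independent two-component mixing calculation."""

    @staticmethod
    def brute_force_mix(base, spec, water, added):
        total = 100.0 + water + added
        comp = {v: base[v] for v in ("protein", "fat", "ts", "snf", "lactose")}
        comp["protein"] += added * (spec.protein_fraction + 6.38 * spec.nitrogen_fraction)
        solids = added * spec.solids_fraction
        comp["ts"] += solids
        comp["snf"] += solids
        if spec.category == "carbohydrate":
            comp["lactose"] += solids
        return {v: m / total * 100.0 for v, m in comp.items()}

    def test_random_recipes_agree_with_oracle(self, pool_b, specs):
        rng = np.random.default_rng(2024)
        codes = list(specs)
        for _ in range(20):
            code = codes[rng.integers(len(codes))]
            water = float(rng.uniform(0, 40))
            added = 0.0 if code == "WATER" else float(rng.uniform(0, 4))
            recipe = AdulterationRecipe(
                "B", code, "single", level=1, added_mass=added, water_added=water
            )
            out = apply_recipe(pool_b, recipe, specs[code])
            expect = self.brute_force_mix(pool_b, specs[code], water, added)
            for v, m in expect.items():
                assert out[v] == pytest.approx(m, abs=1e-9), (code, v)

    def test_conservation_of_mass_fractions(self, adulterant_set):
        # every % w/w channel stays a fraction of the total mass
        pct = adulterant_set[["protein", "fat", "ts", "snf", "lactose"]]
        assert (pct.to_numpy() >= -1e-12).all()
        assert (pct.to_numpy() <= 100 + 1e-12).all()
        assert (adulterant_set["snf"] <= adulterant_set["ts"] + 1e-12).all()


class TestCombinedDose:
    def test_pure_protein_adulterant_dose_is_40pct_of_protein_mass(self, pool_b):
        from milkscreen.adulteration import AdulterantSpec

        pure = AdulterantSpec("WPI", "protein_rich", protein_fraction=1.0, solids_fraction=1.0)
        dose = combined_dose(pool_b, pure, TARGET_PROTEIN)
        assert dose == pytest.approx(0.40 * pool_b["protein"], abs=1e-12)

    def test_zero_boost_needs_zero_dose(self, pool_b, specs):
        assert combined_dose(pool_b, specs["URE"], TARGET_PROTEIN, boost=0.0) == 0.0

    def test_melamine_needs_less_than_urea(self, pool_b, specs):
        d_mlm = combined_dose(pool_b, specs["MLM"], TARGET_PROTEIN)
        d_ure = combined_dose(pool_b, specs["URE"], TARGET_PROTEIN)
        assert d_mlm < d_ure
        # inverse proportionality to the nitrogen fraction
        assert d_mlm / d_ure == pytest.approx(
            specs["URE"].nitrogen_fraction / specs["MLM"].nitrogen_fraction, rel=1e-9
        )

    def test_no_contribution_to_target_channel_rejected(self, pool_b, specs):
        with pytest.raises(ValueError, match="contributes nothing"):
            combined_dose(pool_b, specs["WATER"], TARGET_TS)


def test_adulterant_test_set_shape(adulterant_set):
    assert len(adulterant_set) == 339
    assert adulterant_set["sample_id"].is_unique
    by_mode = adulterant_set["mode"].value_counts()
    assert by_mode["single"] == 288 and by_mode["combined"] == 51
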