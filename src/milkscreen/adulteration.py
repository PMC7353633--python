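"""Mass-balance simulation of milk adulteration.

The experimental design covers 24 adulterants in five categories
(protein-rich powders, nitrogen-rich compounds, carbohydrates,
preservatives/concealers, and water), applied to each of the three
control pools: four single-adulteration levels per substance
(24 × 4 × 3 = 288 samples), plus combined adulterations in which 40 g of
water is first added to 100 g of pool milk and a protein-rich, nitrogen
or carbohydrate adulterant is then dosed to lift the apparent protein
(or, for carbohydrates, apparent total solids) by 40% w/w
((5 + 5 + 7) × 3 = 51 samples), for 339 adulterated samples in total.

Apparent composition is predicted by two-component mass balance:

* every % w/w channel is (component mass) / (total mass) × 100;
* nitrogen compounds inflate apparent protein by 6.38 g per g nitrogen
  (the Kjeldahl dairy factor — FTIR/Kjeldahl protein readings respond to
  nitrogen, not to true protein);
* carbohydrates inflate the apparent lactose (carbohydrate) channel;
* density rises linearly with added solids (3.7 g/L per 1% w/w) and is
  diluted toward 1000 g/L (water) otherwise;
* the freezing-point depression scales with the solute concentration of
  the aqueous phase: dilution shrinks it proportionally, and dissolved
  low-molar-mass adulterants add 1.86 °C·kg/mol × molality × particles
  per formula unit.  Polymers (starch, maltodextrin, arrowroot) and
  proteins contribute negligibly and carry no cryoscopic term.

Per-level doses are configurable; the defaults are 10/20/30/40 g water,
0.5/1/2/4 g solids and 0.05/0.1/0.2/0.4 g preservative per 100 g milk.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .schema import FEATURES

KJELDAHL_FACTOR = 6.38
CRYOSCOPIC_CONSTANT = 1.86  # °C·kg/mol, water
DENSITY_PER_SOLIDS = 3.7    # g/L per 1 % w/w added solids
WATER_DENSITY_BASE = 1000.0  # g/L

CATEGORY_ORDER = ("protein_rich", "nitrogen", "carbohydrate", "preservative", "water")
#: Categories taking part in the combined (water + adulterant) design.
COMBINED_CATEGORIES = ("protein_rich", "nitrogen", "carbohydrate")

DEFAULT_DOSES: dict[str, tuple[float, ...]] = {
    "protein_rich": (0.5, 1.0, 2.0, 4.0),
    "nitrogen": (0.5, 1.0, 2.0, 4.0),
    "carbohydrate": (0.5, 1.0, 2.0, 4.0),
    "preservative": (0.05, 0.1, 0.2, 0.4),
    "water": (10.0, 20.0, 30.0, 40.0),
}

COMBINED_WATER = 40.0       # g per 100 g milk
COMBINED_BOOST = 0.40       # +40 % w/w apparent protein or TS

TARGET_NONE = "none"
TARGET_PROTEIN = "apparent_protein_+40%"
TARGET_TS = "apparent_ts_+40%"


@dataclass(frozen=True)
class AdulterantSpec:
    """Composition constants of one adulterant."""

    code: str
    category: str
    nitrogen_fraction: float = 0.0
    protein_fraction: float = 0.0
    solids_fraction: float = 0.0
    molar_mass: float = 0.0
    dissociation_count: int = 0

    def __post_init__(self):
        if self.category not in CATEGORY_ORDER:
            raise ValueError(f"unknown adulterant category {self.category!r}")
        for f in (self.nitrogen_fraction, self.protein_fraction, self.solids_fraction):
            if not 0 <= f <= 1:
                raise ValueError("composition fractions must lie in [0, 1]")

    @property
    def protein_equivalent(self) -> float:
        """Apparent-protein g per g of adulterant (true protein + N × 6.38)."""
        return self.protein_fraction + KJELDAHL_FACTOR * self.nitrogen_fraction


@dataclass(frozen=True)
class AdulterationRecipe:
    """One prepared adulterated sample: what was added to which pool."""

    pool_id: str
    code: str
    mode: str                     # "single" | "combined"
    level: int | None = None      # 1..4, single mode only
    added_mass: float | None = None  # g per 100 g milk (None: solve at apply time)
    water_added: float = 0.0      # g per 100 g milk
    target: str = TARGET_NONE

    def __post_init__(self):
        if self.mode == "single":
            if self.level is None or not 1 <= self.level:
                raise ValueError("single recipes need a positive level")
            if self.target != TARGET_NONE:
                raise ValueError("single recipes carry no combined target")
        elif self.mode == "combined":
            if self.level is not None:
                raise ValueError("combined recipes have no level")
            if self.target not in (TARGET_PROTEIN, TARGET_TS):
                raise ValueError("combined recipes need a +40% target")
        else:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.added_mass is not None and self.added_mass < 0:
            raise ValueError("added_mass must be non-negative")


def registry_specs(registry: pd.DataFrame) -> dict[str, AdulterantSpec]:
    """Convert the registry table into :class:`AdulterantSpec` objects."""
    return {
        code: AdulterantSpec(
            code=code,
            category=row["category"],
            nitrogen_fraction=float(row["nitrogen_fraction"]),
            protein_fraction=float(row["protein_fraction"]),
            solids_fraction=float(row["solids_fraction"]),
            molar_mass=float(row["molar_mass"]),
            dissociation_count=int(row["dissociation_count"]),
        )
        for code, row in registry.iterrows()
    }


def enumerate_design(
    pool_ids,
    registry: pd.DataFrame,
    doses: dict[str, tuple[float, ...]] | None = None,
) -> list[AdulterationRecipe]:
    """Enumerate the full adulteration design, deterministically ordered.

    Ordering is (pool, category, code within category, level), singles
    before combined recipes.  A full registry yields 288 + 51 recipes.
    """
    doses = {**DEFAULT_DOSES, **(doses or {})}
    specs = registry_specs(registry)
    by_cat: dict[str, list[str]] = {c: [] for c in CATEGORY_ORDER}
    for code, spec in specs.items():
        by_cat[spec.category].append(code)

    singles = [
        AdulterationRecipe(
            pool_id=pid, code=code, mode="single", level=lvl + 1, added_mass=dose
        )
        for pid in pool_ids
        for cat in CATEGORY_ORDER
        for code in by_cat[cat]
        for lvl, dose in enumerate(doses[cat])
    ]
    combined = [
        AdulterationRecipe(
            pool_id=pid, code=code, mode="combined",
            water_added=COMBINED_WATER,
            target=TARGET_TS if cat == "carbohydrate" else TARGET_PROTEIN,
        )
        for pid in pool_ids
        for cat in COMBINED_CATEGORIES
        for code in by_cat[cat]
    ]
    return singles + combined


def combined_dose(base, spec: AdulterantSpec, target: str,
                  water_added: float = COMBINED_WATER,
                  boost: float = COMBINED_BOOST) -> float:
    """Adulterant mass (g) lifting the diluted milk's target channel by ``boost``.

    The dose is defined through the adulterant-to-milk content ratio: the
    adulterant's apparent-protein (or total-solids) contribution must equal
    ``boost`` × the milk's protein (or TS) mass, which dilution leaves
    unchanged.
    """
    base = pd.Series(base)
    if target == TARGET_PROTEIN:
        per_gram = spec.protein_equivalent
        milk_mass = float(base["protein"])
    elif target == TARGET_TS:
        per_gram = spec.solids_fraction
        milk_mass = float(base["ts"])
    elif target == TARGET_NONE:
        return 0.0
    else:
        raise ValueError(f"unknown target {target!r}")
    if per_gram <= 0:
        raise ValueError(f"{spec.code} contributes nothing to the {target} channel")
    return boost * milk_mass / per_gram


def apply_recipe(base, recipe: AdulterationRecipe, spec: AdulterantSpec) -> pd.Series:
    """Apparent composition of ``base`` milk after applying ``recipe``.

    ``base`` holds the seven features of 100 g of pool milk (% w/w, g/L,
    °C).  Returns a new record; the input is untouched.
    """
    base = pd.Series(base)
    if spec.code != recipe.code:
        raise ValueError("recipe/spec code mismatch")
    a = recipe.added_mass
    if a is None:
        a = combined_dose(base, spec, recipe.target, recipe.water_added)
    if a < 0:
        raise ValueError("added_mass must be non-negative")
    if spec.category == "water":
        # dosing "water" means pure dilution regardless of the recipe fields
        a, water = 0.0, recipe.water_added + (recipe.added_mass or 0.0)
    else:
        water = recipe.water_added

    milk = 100.0
    total = milk + water + a
    f = milk / total  # dilution of every milk-borne component

    protein = (base["protein"] + a * spec.protein_equivalent) / total * 100.0
    fat = base["fat"] * f
    added_solids = a * spec.solids_fraction
    ts = (base["ts"] + added_solids) / total * 100.0
    snf = (base["snf"] + added_solids) / total * 100.0
    carb = added_solids if spec.category == "carbohydrate" else 0.0
    lactose = (base["lactose"] + carb) / total * 100.0

    density = (
        WATER_DENSITY_BASE
        + (base["density"] - WATER_DENSITY_BASE) * f
        + DENSITY_PER_SOLIDS * (added_solids / total * 100.0)
    )

    milk_water = milk - base["ts"]           # aqueous phase of the milk, g
    water_total = milk_water + water
    fpd = base["fpd"] * (milk_water / water_total)
    if spec.molar_mass > 0 and spec.dissociation_count > 0:
        molality = (a / spec.molar_mass) * spec.dissociation_count / (water_total / 1000.0)
        fpd += CRYOSCOPIC_CONSTANT * molality

    return pd.Series(
        {"protein": protein, "fat": fat, "ts": ts, "snf": snf,
         "lactose": lactose, "density": density, "fpd": fpd}
    )


def make_adulterant_test_set(
    pools,
    registry: pd.DataFrame,
    doses: dict[str, tuple[float, ...]] | None = None,
) -> pd.DataFrame:
    """Simulate the full 339-sample adulterant test set.

    ``pools`` is a list of :class:`~milkscreen.datasets.PoolProfile`.
    Returns one record per recipe with the recipe metadata alongside the
    seven predicted features.  Predicted values may exceed the plausible
    range of a genuine-milk record (that is the point), so no genuine-milk
    schema validation is applied.
    """
    specs = registry_specs(registry)
    base_by_pool = {p.pool_id: pd.Series({v: p.means[v] for v in FEATURES}) for p in pools}
    recipes = enumerate_design(list(base_by_pool), registry, doses)
    rows = []
    for r in recipes:
        rec = apply_recipe(base_by_pool[r.pool_id], r, specs[r.code])
        tag = f"L{r.level}" if r.mode == "single" else "C"
        rows.append({
            "sample_id": f"{r.pool_id}-{r.code}-{tag}",
            **rec.to_dict(),
            "pool_id": r.pool_id,
            "code": r.code,
            "category": specs[r.code].category,
            "mode": r.mode,
            "level": r.level,
            "water_added": r.water_added,
            "added_mass": r.added_mass if r.added_mass is not None
            else combined_dose(base_by_pool[r.pool_id], specs[r.code], r.target),
            "origin": "adulterated",
        })
    return pd.DataFrame(rows)
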