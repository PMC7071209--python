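"""Food composition database, GI assignment and mixed-meal GI/GL arithmetic.

A food's glycemic index (GI) quantifies, per gram of available carbohydrate,
how strongly it raises blood glucose relative to a reference food (glucose or
white bread).  For a composite dish or a whole meal the GI is the
carbohydrate-weighted mean of its items' GIs, and the glycemic load (GL) of a
consumed portion is::

    gi_meal = sum_i gi_i * carbo_i / sum_i carbo_i
    gl      = (1/100) * sum_i gi_i * carbo_i

where ``carbo_i`` is the grams of carbohydrate contributed by item *i* in the
consumed portion.  These two definitions are linked by the exact identity
``gl = gi_meal * carbo_total / 100``.

GI values rarely come measured for every entry of a national food table, so
entries are filled in through a fixed assignment hierarchy (published value,
zero for carbohydrate-free foods, close botanical/culinary match, food-subgroup
mean, expert default); the rule that fired is kept as a provenance tag.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "GI_RULES",
    "GI_MAX",
    "ZERO_CARB_THRESHOLD",
    "FoodItem",
    "DishRecipe",
    "MealComposition",
    "FoodDB",
    "UndefinedGIError",
    "UnknownFoodError",
    "assign_gi",
    "dish_gi",
    "meal_composition",
    "read_food_table",
    "read_recipes",
    "load_bundled_food_db",
]

#: Assignment provenance tags, in priority order.
GI_RULES = ("published", "zero_carb", "close_match", "subgroup_mean", "expert_default")

#: Upper validation bound for GI; published values exceed 100 for a few foods.
GI_MAX = 150.0

#: Foods with less available carbohydrate than this (g/100 g) get GI 0.
ZERO_CARB_THRESHOLD = 5.0

NUTRIENT_FIELDS = (
    "carb_per100",
    "prot_per100",
    "fat_per100",
    "kcal_per100",
    "water_per100",
    "starch_per100",
    "fiber_per100",
)


class UndefinedGIError(ValueError):
    """An operation required a GI that is not defined for some food item."""


class UnknownFoodError(KeyError):
    """A meal references a food name absent from the database."""


@dataclass(frozen=True)
class FoodItem:
    """One food-table entry: per-100 g composition plus GI and its provenance."""

    name: str
    carb_per100: float
    prot_per100: float = 0.0
    fat_per100: float = 0.0
    kcal_per100: float = 0.0
    water_per100: float = 0.0
    starch_per100: float = 0.0
    fiber_per100: float = 0.0
    gi: float | None = None
    gi_rule: str | None = None

    def __post_init__(self) -> None:
        for f in NUTRIENT_FIELDS:
            v = getattr(self, f)
            if v < 0:
                raise ValueError(f"{self.name}: {f} must be >= 0, got {v}")
        if self.carb_per100 > 100:
            raise ValueError(f"{self.name}: carb_per100 > 100 g/100 g")
        if self.gi is not None and not (0.0 <= self.gi <= GI_MAX):
            raise ValueError(f"{self.name}: gi {self.gi} outside [0, {GI_MAX}]")
        if self.gi_rule is not None and self.gi_rule not in GI_RULES:
            raise ValueError(f"{self.name}: unknown gi_rule {self.gi_rule!r}")
        if self.gi_rule == "zero_carb" and self.gi != 0.0:
            raise ValueError(f"{self.name}: zero_carb rule requires gi = 0")

    @property
    def gi_defined(self) -> bool:
        return self.gi is not None


@dataclass(frozen=True)
class DishRecipe:
    """A complex dish as mass fractions of its ingredient foods."""

    name: str
    ingredients: tuple[tuple[FoodItem, float], ...]

    def __post_init__(self) -> None:
        if not self.ingredients:
            raise ValueError(f"{self.name}: recipe needs at least one ingredient")
        total = sum(frac for _, frac in self.ingredients)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"{self.name}: mass fractions sum to {total}, not 1")

    def as_food_item(self) -> FoodItem:
        """Collapse the recipe into a per-100 g composite food.

        The dish GI comes from :func:`dish_gi`; it is left undefined if any
        carbohydrate-bearing ingredient lacks a GI.
        """
        per100 = {f: sum(frac * getattr(food, f) for food, frac in self.ingredients)
                  for f in NUTRIENT_FIELDS}
        try:
            gi = dish_gi(self)
            rule = "published"  # derived from ingredient GIs, not re-assigned
        except UndefinedGIError:
            gi, rule = None, None
        return FoodItem(name=self.name, gi=gi, gi_rule=rule, **per100)


@dataclass(frozen=True)
class MealComposition:
    """Nutrient totals of a consumed meal (grams / kcal) plus its GI and GL.

    ``gi``/``gl`` are NaN and ``gi_defined`` False when any item with
    carbohydrate lacks a GI; such meals are kept through matching and removed
    later by the record filter.
    """

    carbo: float
    prot: float
    fat: float
    kcal: float
    water: float
    starch: float
    fiber: float
    gi: float
    gl: float
    gi_defined: bool = True

    def __add__(self, other: "MealComposition") -> "MealComposition":
        carbo = self.carbo + other.carbo
        defined = self.gi_defined and other.gi_defined
        gl = self.gl + other.gl if defined else float("nan")
        gi = (100.0 * gl / carbo if carbo > 0 else 0.0) if defined else float("nan")
        return MealComposition(
            carbo=carbo,
            prot=self.prot + other.prot,
            fat=self.fat + other.fat,
            kcal=self.kcal + other.kcal,
            water=self.water + other.water,
            starch=self.starch + other.starch,
            fiber=self.fiber + other.fiber,
            gi=gi,
            gl=gl,
            gi_defined=defined,
        )


def assign_gi(
    item: FoodItem,
    published_gi: float | None = None,
    close_match_gi: float | None = None,
    subgroup_mean_gi: float | None = None,
    expert_default: float | None = None,
) -> FoodItem:
    """Assign a GI to ``item`` by the first applicable rule of the hierarchy.

    Order: (1) published GI; (2) GI 0 when carbohydrate < 5 g/100 g;
    (3) GI of a close match; (4) subgroup mean GI; (5) expert default.
    The winning rule is recorded in ``gi_rule``.  If no rule applies the GI
    stays undefined and downstream record filtering removes the meals that
    contain the item.
    """
    for candidate in (published_gi, close_match_gi, subgroup_mean_gi, expert_default):
        if candidate is not None and candidate < 0:
            raise ValueError(f"negative candidate GI {candidate} for {item.name}")
    if published_gi is not None:
        return replace(item, gi=float(published_gi), gi_rule="published")
    if item.carb_per100 < ZERO_CARB_THRESHOLD:
        return replace(item, gi=0.0, gi_rule="zero_carb")
    if close_match_gi is not None:
        return replace(item, gi=float(close_match_gi), gi_rule="close_match")
    if subgroup_mean_gi is not None:
        return replace(item, gi=float(subgroup_mean_gi), gi_rule="subgroup_mean")
    if expert_default is not None:
        return replace(item, gi=float(expert_default), gi_rule="expert_default")
    return replace(item, gi=None, gi_rule=None)


def dish_gi(recipe: DishRecipe) -> float:
    """Carbohydrate-weighted mean GI of a dish's ingredients.

    ``carbo_i = mass_fraction_i * carb_per100_i`` is the carbohydrate each
    ingredient contributes per 100 g of dish.  An all-zero-carbohydrate dish
    returns 0 by convention (consistent with assigning GI 0 to
    carbohydrate-free foods).
    """
    num = 0.0
    den = 0.0
    for food, frac in recipe.ingredients:
        carbo_i = frac * food.carb_per100
        if carbo_i > 0 and not food.gi_defined:
            raise UndefinedGIError(food.name)
        if food.gi_defined:
            num += food.gi * carbo_i
        den += carbo_i
    if den == 0.0:
        return 0.0
    return num / den


def meal_composition(
    meal: Sequence[tuple[str, float]],
    db: "FoodDB",
) -> MealComposition:
    """Nutrient totals, GI and GL of a meal given as (food name, grams) pairs.

    Each nutrient is ``sum_i grams_i * per100_i / 100``.  GL is
    ``(1/100) * sum_i gi_i * carbo_i`` with ``carbo_i`` the grams of
    carbohydrate item *i* contributes; the meal GI is the carbohydrate-weighted
    mean of item GIs.  A meal containing a carbohydrate-bearing item with
    undefined GI is returned with ``gi_defined=False`` (NaN gi/gl) rather than
    raised, so it can flow through matching and be removed by the record
    filter.
    """
    totals = dict.fromkeys(NUTRIENT_FIELDS, 0.0)
    gi_carbo = 0.0  # sum gi_i * carbo_i
    defined = True
    for name, grams in meal:
        if grams <= 0:
            raise ValueError(f"grams must be > 0 for {name!r}")
        food = db.resolve(name)
        for f in NUTRIENT_FIELDS:
            totals[f] += grams * getattr(food, f) / 100.0
        carbo_i = grams * food.carb_per100 / 100.0
        if food.gi_defined:
            gi_carbo += food.gi * carbo_i
        elif carbo_i > 0:
            defined = False
    carbo = totals["carb_per100"]
    if defined:
        gl = gi_carbo / 100.0
        gi = 100.0 * gl / carbo if carbo > 0 else 0.0
    else:
        gl = gi = float("nan")
    return MealComposition(
        carbo=carbo,
        prot=totals["prot_per100"],
        fat=totals["fat_per100"],
        kcal=totals["kcal_per100"],
        water=totals["water_per100"],
        starch=totals["starch_per100"],
        fiber=totals["fiber_per100"],
        gi=gi,
        gl=gl,
        gi_defined=defined,
    )


class FoodDB:
    """Lookup of food names to :class:`FoodItem`, with dish recipes resolved."""

    def __init__(self, foods: Iterable[FoodItem], recipes: Iterable[DishRecipe] = ()):
        self._foods: dict[str, FoodItem] = {}
        for food in foods:
            if food.name in self._foods:
                raise ValueError(f"duplicate food name {food.name!r}")
            self._foods[food.name] = food
        for recipe in recipes:
            if recipe.name in self._foods:
                raise ValueError(f"duplicate name {recipe.name!r} (dish vs food)")
            self._foods[recipe.name] = recipe.as_food_item()

    def resolve(self, name: str) -> FoodItem:
        try:
            return self._foods[name]
        except KeyError:
            raise UnknownFoodError(name) from None

    def __contains__(self, name: str) -> bool:
        return name in self._foods

    def __len__(self) -> int:
        return len(self._foods)

    @property
    def names(self) -> list[str]:
        return list(self._foods)

    def items(self) -> list[FoodItem]:
        return list(self._foods.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "name": f.name,
                **{c: getattr(f, c) for c in NUTRIENT_FIELDS},
                "gi": f.gi if f.gi is not None else "",
                "gi_rule": f.gi_rule or "",
            }
            for f in self._foods.values()
        ]
        return pd.DataFrame(rows)


FOOD_TABLE_COLUMNS = ["name", *NUTRIENT_FIELDS, "gi", "gi_rule"]


def read_food_table(path: str | Path) -> list[FoodItem]:
    """Read a food-table CSV (blank gi = undefined)."""
    df = pd.read_csv(path, dtype={"name": str, "gi_rule": str})
    missing = set(FOOD_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    foods = []
    for _, row in df.iterrows():
        gi = None if pd.isna(row["gi"]) or row["gi"] == "" else float(row["gi"])
        rule = row["gi_rule"] if isinstance(row["gi_rule"], str) and row["gi_rule"] else None
        foods.append(
            FoodItem(
                name=row["name"],
                gi=gi,
                gi_rule=rule,
                **{c: float(row[c]) for c in NUTRIENT_FIELDS},
            )
        )
    return foods


def read_recipes(path: str | Path, foods: Mapping[str, FoodItem] | "FoodDB") -> list[DishRecipe]:
    """Read a recipe CSV with columns dish_name, ingredient_name, mass_fraction."""
    df = pd.read_csv(path, dtype={"dish_name": str, "ingredient_name": str})
    lookup = foods.resolve if isinstance(foods, FoodDB) else foods.__getitem__
    recipes = []
    for dish, grp in df.groupby("dish_name", sort=False):
        ingredients = tuple(
            (lookup(r["ingredient_name"]), float(r["mass_fraction"]))
            for _, r in grp.iterrows()
        )
        recipes.append(DishRecipe(name=dish, ingredients=ingredients))
    return recipes


def load_bundled_food_db() -> FoodDB:
    """The fixture food table shipped with the package (~50 items across the
    five GI assignment strata, including a few GI-undefined entries)."""
    from importlib.resources import files

    data = files("ppgr_pipeline") / "data"
    foods = read_food_table(str(data / "food_table.csv"))
    db = FoodDB(foods)
    recipes = read_recipes(str(data / "recipes.csv"), db)
    return FoodDB(foods, recipes)
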