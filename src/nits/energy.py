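"""Energy-expenditure computations for the daily-balance task.

Basal metabolic rate by the Mifflin-St Jeor equation (height in metres),
total daily energy expenditure as BMR times a physical-activity-level
multiplier, calories gained from a food diary (per-100 g calorie norms),
calories burned from an activity diary (MET coefficients), and the daily
calorie balance.  A persistent negative balance is a known sign of
hypermetabolic neurodegenerative disease, which is why the balance feeds
the impairment feature table.
"""

from __future__ import annotations

from dataclasses import dataclass

from nits.session_io import SubjectProfile

#: conventional physical-activity-level multipliers (config-overridable)
PAL_COEFFICIENTS = {
    "sedentary": 1.2,
    "light": 1.375,
    "moderate": 1.55,
    "heavy": 1.725,
    "athlete": 1.9,
}


@dataclass(frozen=True)
class ProductItem:
    name: str
    grams: float
    kcal_per_100g: float
    mealtime: str = "dinner"

    def __post_init__(self) -> None:
        if self.grams <= 0:
            raise ValueError("grams must be positive")
        if self.kcal_per_100g < 0:
            raise ValueError("kcal_per_100g must be >= 0")
        if self.mealtime not in ("breakfast", "dinner", "supper"):
            raise ValueError(f"unknown mealtime {self.mealtime!r}")


@dataclass(frozen=True)
class ActivityItem:
    name: str
    met: float
    minutes: float
    time_of_day: str = "day"

    def __post_init__(self) -> None:
        if self.met <= 0 or self.minutes <= 0:
            raise ValueError("met and minutes must be positive")
        if self.time_of_day not in ("morning", "day", "evening"):
            raise ValueError(f"unknown time_of_day {self.time_of_day!r}")


@dataclass(frozen=True)
class EnergyReport:
    bmr: float
    tdee: float
    p_gained: float
    p_burned: float
    p_balance: float


def bmr(profile: SubjectProfile) -> float:
    """Mifflin-St Jeor basal metabolic rate, kcal/day.

    men:   625*H + 10*W - 5*A + 5
    women: 625*H + 10*W - 5*A - 161     (H in metres, W in kg, A in years)
    """
    base = 625.0 * profile.height_m + 10.0 * profile.weight_kg - 5.0 * profile.age_years
    return base + (5.0 if profile.gender == "man" else -161.0)


def tdee(bmr_value: float, pal: str, coefficients: dict[str, float] | None = None) -> float:
    """Total daily energy expenditure: BMR times the PAL multiplier."""
    if bmr_value <= 0:
        raise ValueError("bmr_value must be positive")
    coeffs = PAL_COEFFICIENTS if coefficients is None else coefficients
    if pal not in coeffs:
        raise ValueError(f"unknown PAL {pal!r}")
    return bmr_value * coeffs[pal]


def p_gained(items: list[ProductItem]) -> float:
    """Daily calories gained from the food diary: sum grams*Cal100/100."""
    return sum(it.grams * it.kcal_per_100g / 100.0 for it in items)


def p_burned(activities: list[ActivityItem], weight_kg: float) -> float:
    """Daily calories burned: sum MET_i * W * D / 60 over the diary."""
    if weight_kg <= 0:
        raise ValueError("weight_kg must be positive")
    return sum(a.met * weight_kg * a.minutes / 60.0 for a in activities)


def p_balance(gained: float, burned: float) -> float:
    """Daily calorie balance; negative values flag a negative energy balance."""
    return gained - burned


def energy_report(
    profile: SubjectProfile,
    items: list[ProductItem],
    activities: list[ActivityItem],
) -> EnergyReport:
    """Full daily energy report for one subject diary."""
    b = bmr(profile)
    t = tdee(b, profile.pal)
    g = p_gained(items)
    u = p_burned(activities, profile.weight_kg)
    return EnergyReport(bmr=b, tdee=t, p_gained=g, p_burned=u, p_balance=p_balance(g, u))
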