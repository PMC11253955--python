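"""Food and beverage category scheme.

Purchases are aggregated into 4 beverage and 7 food categories; demand
regressions include the log price of all 11.  The tax applies to the
``ssb`` category only.
"""

BEVERAGE_CATEGORIES: tuple[str, ...] = ("ssb", "unsweetened", "alcoholic", "diet")

FOOD_CATEGORIES: tuple[str, ...] = (
    "fruits",
    "in_natura",
    "meat",
    "snacks",
    "sugar",
    "processed",
    "other_food",
)

ALL_CATEGORIES: tuple[str, ...] = BEVERAGE_CATEGORIES + FOOD_CATEGORIES

TAXED_CATEGORY = "ssb"

TERTILES: tuple[int, ...] = (1, 2, 3)
TERTILE_LABELS: dict[int, str] = {1: "low", 2: "middle", 3: "high"}

SEXES: tuple[str, ...] = ("female", "male")
AGE_GROUPS: tuple[str, ...] = ("20-39", "40-59", "60+")


def age_group(age) -> str:
    """Map an adult age in years to its analysis age band."""
    if age < 20:
        raise ValueError(f"adult age bands start at 20, got {age}")
    if age < 40:
        return "20-39"
    if age < 60:
        return "40-59"
    return "60+"
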