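"""Controlled vocabularies shared across the pipeline.

The 23 natural compounds (NCs) are the dietary nutrients whose daily
intake is estimated from food-frequency questionnaires and related to
circulating miRNA levels.  Each NC belongs to one of three classes used
for reporting and network colouring: lipid-related, micro-element, or
vitamin-related.
"""

from __future__ import annotations

#: Canonical diet groups, in the order used for trend classification.
DIET_GROUPS: tuple[str, ...] = ("omnivore", "vegetarian", "vegan")

#: The 23 natural compounds tracked by the intake estimation stage.
NATURAL_COMPOUNDS: tuple[str, ...] = (
    "beta_carotene",
    "calcium",
    "cholesterol",
    "folic_acid",
    "iron",
    "linoleic_acid",
    "linolenic_acid",
    "monounsaturated_fatty_acids",
    "niacin",
    "oleic_acid",
    "phosphorus",
    "potassium",
    "retinol",
    "riboflavin",
    "sodium",
    "thiamine",
    "total_polyunsaturated_fatty_acids",
    "total_saturated_fatty_acids",
    "vitamin_b6",
    "vitamin_c",
    "vitamin_d",
    "vitamin_e",
    "zinc",
)

LIPID_RELATED: frozenset[str] = frozenset(
    {
        "cholesterol",
        "linoleic_acid",
        "linolenic_acid",
        "monounsaturated_fatty_acids",
        "oleic_acid",
        "total_polyunsaturated_fatty_acids",
        "total_saturated_fatty_acids",
    }
)
MICRO_ELEMENTS: frozenset[str] = frozenset(
    {"calcium", "iron", "phosphorus", "potassium", "sodium", "zinc"}
)
VITAMIN_RELATED: frozenset[str] = frozenset(
    {
        "beta_carotene",
        "folic_acid",
        "niacin",
        "retinol",
        "riboflavin",
        "thiamine",
        "vitamin_b6",
        "vitamin_c",
        "vitamin_d",
        "vitamin_e",
    }
)

#: NC id -> class label, covering the full canonical vocabulary.
NC_CLASSES: dict[str, str] = {
    **{nc: "lipid-related" for nc in LIPID_RELATED},
    **{nc: "micro-element" for nc in MICRO_ELEMENTS},
    **{nc: "vitamin-related" for nc in VITAMIN_RELATED},
}

#: Normalized-read threshold for calling a miRNA detectable / analyzable.
DETECTABILITY_THRESHOLD: float = 15.0


def nc_names(n_nc: int) -> list[str]:
    """Return ``n_nc`` NC identifiers.

    The first 23 come from the canonical vocabulary; additional ids are
    generated as ``nc_24``, ``nc_25``, ... for oversized synthetic runs.
    """
    if n_nc < 1:
        raise ValueError("n_nc must be >= 1")
    names = list(NATURAL_COMPOUNDS[:n_nc])
    names += [f"nc_{k}" for k in range(len(names) + 1, n_nc + 1)]
    return names


def nc_class(nc_id: str) -> str:
    """Class label for an NC id (``none`` for non-canonical ids)."""
    return NC_CLASSES.get(nc_id, "none")
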