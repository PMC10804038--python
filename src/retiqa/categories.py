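"""Quality-category vocabulary shared by all modules.

Colour fundus (CF) images are graded in contrast, focus, illumination and
shadow & reflection; fluorescein angiography (FA) in contrast, focus and
noise.  Both modalities additionally carry an overall-quality grade.  Grades
are ordinal Likert values from 1 (best) to 5 (worst); a grade of 1-2 counts
as good image quality, 3-5 as poor.
"""

from __future__ import annotations

MODALITIES = ("CF", "FA")

#: per-modality category order; "overall" is always last
CF_CATEGORIES = ("contrast", "focus", "illumination", "shadow_reflection", "overall")
FA_CATEGORIES = ("contrast", "focus", "noise", "overall")

GOOD = "good"
POOR = "poor"

#: fixed order in which degradations are composed onto a phantom
DEGRADATION_ORDER = ("contrast", "focus", "illumination", "shadow_reflection", "noise")

#: manifest column order for Likert labels (union over modalities)
ALL_LIKERT_COLUMNS = (
    "likert_contrast",
    "likert_focus",
    "likert_illumination",
    "likert_shadow_reflection",
    "likert_noise",
    "likert_overall",
)


def check_modality(modality: str) -> str:
    if modality not in MODALITIES:
        raise ValueError(f"unknown modality {modality!r}; expected one of {MODALITIES}")
    return modality


def categories_for(modality: str) -> tuple[str, ...]:
    """All quality categories of a modality, overall last."""
    check_modality(modality)
    return CF_CATEGORIES if modality == "CF" else FA_CATEGORIES


def degradable_categories(modality: str) -> tuple[str, ...]:
    """The non-overall categories, i.e. those with a physical degradation."""
    return categories_for(modality)[:-1]


def n_categories(modality: str) -> int:
    return len(categories_for(modality))
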