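"""Deterministic serialization of patient records into clinical narratives.

Each record is mapped through a slot-filling prompt template into a short
free-text report that mimics a physician's diagnostic narrative.  The default
template leads with demographics and renal function, flags hypertension as a
comorbidity phrase, and highlights the platelet-to-albumin ratio (PAR) as the
core indicator.  Serialization is pure string substitution: no language model
is involved and the same record always yields the same narrative.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .cohort import PatientRecord
from .errors import TemplateError

__all__ = [
    "Narrative",
    "PromptTemplate",
    "DEFAULT_TEMPLATE_TEXT",
    "serialize",
    "validate_template",
]

DEFAULT_TEMPLATE_TEXT = (
    "Basic Information: {Age} years old {Gender}, history of diabetes for "
    "{History} years. Physical Examination: BMI {BMI}, {BP_Description}. "
    "Renal Function: eGFR is {eGFR} ml/min, Serum Creatinine {SCr} umol/L. "
    "Twenty-four hour proteinuria severity is {Proteinuria} mg. "
    "Serum Albumin {ALB} g/L, BUN {BUN} mmol/L, Uric Acid {UA} umol/L. "
    "Core Indicator: Platelet-to-Albumin Ratio (PAR) is {PAR}. "
    "Metabolic & Hematologic Context: Glucose {Glu} mmol/L, "
    "Lipids (Triglycerides {TG}/Cholesterol {Chol}). "
    "Hemoglobin {Hb} g/L, CRP {CRP} mg/L, Platelets {PLT}, "
    "WBC {WBC} (Neutrophils {NE}%/Lymphocytes {LY}%)."
)

# Map of template placeholder -> record field (None: handled specially).
PLACEHOLDER_FIELDS: Mapping[str, str | None] = {
    "Age": "age",
    "Gender": None,           # capitalized sex
    "History": "diabetes_duration",
    "BMI": "bmi",
    "BP_Description": None,   # hypertension flag -> phrase
    "eGFR": "egfr",
    "SCr": "scr",
    "Proteinuria": None,      # stored g/24h, serialized in mg
    "ALB": "alb",
    "BUN": "bun",
    "UA": "ua",
    "PAR": "par",
    "Glu": "glu",
    "TG": "tg",
    "Chol": "chol",
    "Hb": "hb",
    "CRP": "crp",
    "PLT": "plt",
    "WBC": "wbc",
    "NE": "ne_pct",
    "LY": "ly_pct",
}

_PLACEHOLDER_RE = re.compile(r"\{([A-Za-z_][A-Za-z0-9_]*)\}")


@dataclass(frozen=True)
class Narrative:
    """The serialized clinical text for one patient."""

    patient_id: str
    text: str


@dataclass(frozen=True)
class PromptTemplate:
    """A slot-filling template plus per-field formatting rules.

    ``formatting_rules`` maps placeholder names to format specs (e.g. ".3f");
    unlisted numeric placeholders use "g", which renders values at their
    stored precision without trailing zeros.  ``bp_map`` maps the
    hypertension flag to its narrative phrase; only the hypertensive phrase
    is dictated by the reference narrative style, the normotensive one is a
    package choice.
    """

    template_text: str = DEFAULT_TEMPLATE_TEXT
    formatting_rules: Mapping[str, str] = field(default_factory=dict)
    bp_map: Mapping[bool, str] = field(
        default_factory=lambda: {True: "Comorbid Hypertension", False: "Normal Blood Pressure"}
    )

    @classmethod
    def from_file(cls, path, **kwargs) -> "PromptTemplate":
        text = Path(path).read_text(encoding="utf-8").strip()
        return cls(template_text=text, **kwargs)

    def placeholders(self) -> list[str]:
        return validate_template(self.template_text)


def validate_template(
    template_text: str, required: Sequence[str] | None = None
) -> list[str]:
    """Return placeholders in order of appearance.

    Raises :class:`TemplateError` if a placeholder is not a known record
    slot, or if ``required`` is given and a required slot is absent.
    """
    found = _PLACEHOLDER_RE.findall(template_text)
    unknown = [p for p in found if p not in PLACEHOLDER_FIELDS]
    if unknown:
        raise TemplateError(f"unknown placeholder(s): {', '.join(sorted(set(unknown)))}")
    if required is not None:
        missing = [p for p in required if p not in found]
        if missing:
            raise TemplateError(f"template missing required placeholder(s): {', '.join(missing)}")
    return found


def _format_value(value, spec: str) -> str:
    if spec == "g":
        return format(value, "g") if isinstance(value, float) else str(value)
    return format(value, spec)


def serialize(record: PatientRecord, template: PromptTemplate | None = None) -> Narrative:
    """Render one record through the template into a :class:`Narrative`."""
    template = template or PromptTemplate()
    record.validate()
    validate_template(template.template_text)

    values: dict[str, str] = {}
    for name, fieldname in PLACEHOLDER_FIELDS.items():
        spec = template.formatting_rules.get(name, "g")
        if name == "Gender":
            values[name] = record.sex.capitalize()
        elif name == "BP_Description":
            values[name] = template.bp_map[record.hypertension]
        elif name == "Proteinuria":
            values[name] = str(int(round(record.proteinuria_24h * 1000)))
        else:
            values[name] = _format_value(getattr(record, fieldname), spec)

    text = _PLACEHOLDER_RE.sub(lambda m: values[m.group(1)], template.template_text)
    if _PLACEHOLDER_RE.search(text):
        raise TemplateError("unresolved placeholders remain after substitution")
    return Narrative(patient_id=record.id, text=text)
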