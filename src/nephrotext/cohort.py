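"""Patient cohort model, label derivations, CSV I/O and a synthetic generator.

A cohort is a list of :class:`PatientRecord` objects, one per biopsy-proven
diabetic-nephropathy (DN) patient.  Two prediction targets are derived from
the renal-biopsy reading: the 2010 Renal Pathology Society glomerular class
(I-IV), collapsed to a binary mild (I-II) / severe (III-IV) outcome, and the
interstitial-fibrosis-and-tubular-atrophy (IFTA) score (0-3), re-binned to
mild (0-1) / moderate (2) / severe (3).

The synthetic generator emulates the marginal distributions of a 195-patient
biopsy cohort (group-wise medians/IQRs or means +/- sd per lab) and the
severity-dependent direction of group differences: severe patients have
stochastically higher platelet count, serum creatinine, 24-h proteinuria and
platelet-to-albumin ratio (PAR), and lower hemoglobin and eGFR.  Labs
summarised by median (IQR) are drawn log-normal; labs summarised as
mean +/- sd are drawn from truncated normals.  PAR is always recomputed from
the generated platelet count and albumin, never sampled.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DomainError, ParseError

__all__ = [
    "PatientRecord",
    "LabelScheme",
    "GLOMERULAR_BINARY",
    "IFTA_3CLASS",
    "derive_par",
    "binarize_glomerular",
    "trichotomize_ifta",
    "generate_cohort",
    "read_cohort",
    "write_cohort",
    "cohort_to_frame",
]

# Fixed CSV header; one column per record field, in this order.
CSV_COLUMNS = [
    "id", "age", "sex", "diabetes_duration", "hypertension", "bmi",
    "wbc", "ne_pct", "ly_pct", "hb", "plt", "alb", "crp", "tg", "chol",
    "glu", "bun", "ua", "scr", "egfr", "proteinuria_24h", "par",
    "glomerular_class", "ifta_score",
]

_POSITIVE_LABS = [
    "bmi", "wbc", "ne_pct", "ly_pct", "hb", "plt", "alb", "crp", "tg",
    "chol", "glu", "bun", "ua", "scr", "egfr", "proteinuria_24h", "par",
]


@dataclass(frozen=True)
class PatientRecord:
    """One patient's clinical variables plus pathological labels.

    Units: age and diabetes_duration in years; bmi kg/m2; wbc and plt 10^9/L;
    ne_pct/ly_pct %; hb and alb g/L (note albumin in g/L, not g/dL); crp
    mg/L; tg/chol/glu/bun mmol/L; ua and scr umol/L; egfr mL/min/1.73m2;
    proteinuria_24h g/24h; par dimensionless (plt/alb).
    """

    id: str
    age: int
    sex: str                    # "male" | "female"
    diabetes_duration: float
    hypertension: bool
    bmi: float
    wbc: float
    ne_pct: float
    ly_pct: float
    hb: float
    plt: float
    alb: float
    crp: float
    tg: float
    chol: float
    glu: float
    bun: float
    ua: float
    scr: float
    egfr: float
    proteinuria_24h: float
    par: float
    glomerular_class: int       # 1..4
    ifta_score: int             # 0..3

    def validate(self) -> "PatientRecord":
        if self.sex not in ("male", "female"):
            raise DomainError(f"record {self.id}: sex must be male/female, got {self.sex!r}")
        for name in _POSITIVE_LABS:
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise DomainError(f"record {self.id}: {name} must be strictly positive, got {v}")
        if not 0 <= self.ne_pct <= 100 or not 0 <= self.ly_pct <= 100:
            raise DomainError(f"record {self.id}: differential percentages must lie in [0, 100]")
        if self.egfr < 30:
            raise DomainError(f"record {self.id}: egfr {self.egfr} < 30 (study exclusion)")
        if self.glomerular_class not in (1, 2, 3, 4):
            raise DomainError(f"record {self.id}: glomerular_class must be 1..4")
        if self.ifta_score not in (0, 1, 2, 3):
            raise DomainError(f"record {self.id}: ifta_score must be 0..3")
        # PAR is a derived quantity; tolerate the rounding of stored values.
        if abs(self.par - self.plt / self.alb) > 5e-3 * max(1.0, self.par):
            raise DomainError(
                f"record {self.id}: par={self.par} inconsistent with plt/alb="
                f"{self.plt / self.alb:.4f}"
            )
        return self


@dataclass(frozen=True)
class LabelScheme:
    """A prediction task: which label is used and how it is binned."""

    task: str
    class_names: tuple

    def encode(self, record: PatientRecord) -> int:
        if self.task == "glomerular_binary":
            return self.class_names.index(binarize_glomerular(record.glomerular_class))
        if self.task == "ifta_3class":
            return self.class_names.index(trichotomize_ifta(record.ifta_score))
        raise ConfigError(f"unknown task {self.task!r}")

    def encode_all(self, records: Sequence[PatientRecord]) -> np.ndarray:
        return np.array([self.encode(r) for r in records], dtype=int)


GLOMERULAR_BINARY = LabelScheme("glomerular_binary", ("mild", "severe"))
IFTA_3CLASS = LabelScheme("ifta_3class", ("mild", "moderate", "severe"))


def derive_par(plt: float, alb: float) -> float:
    """Platelet-to-albumin ratio: platelet count (10^9/L) over albumin (g/L)."""
    if not plt > 0:
        raise DomainError(f"platelet count must be positive, got {plt}")
    if not alb > 0:
        raise DomainError(f"albumin must be positive, got {alb}")
    return plt / alb


def binarize_glomerular(glomerular_class: int) -> str:
    """Collapse glomerular class I-IV to mild (I-II) vs severe (III-IV)."""
    if glomerular_class in (1, 2):
        return "mild"
    if glomerular_class in (3, 4):
        return "severe"
    raise DomainError(f"glomerular class must be in 1..4, got {glomerular_class}")


def trichotomize_ifta(score: int) -> str:
    """Re-bin the IFTA score: 0-1 mild, 2 moderate, 3 severe."""
    if score in (0, 1):
        return "mild"
    if score == 2:
        return "moderate"
    if score == 3:
        return "severe"
    raise DomainError(f"IFTA score must be in 0..3, got {score}")


# ---------------------------------------------------------------------------
# Synthetic cohort generation
# ---------------------------------------------------------------------------

# Group-wise marginal summaries (mild = glomerular I-II, severe = III-IV).
# ("ln", median, q1, q3)  -> log-normal matched to the printed median/IQR
# ("tn", mean, sd, lo, hi) -> normal truncated to [lo, hi]
_STRATUM_PARAMS = {
    "mild": {
        "age": ("ln", 53, 40, 62),
        "diabetes_duration": ("ln", 10.0, 5.0, 16.0),
        "bmi": ("ln", 25.34, 23.95, 27.22),
        "wbc": ("ln", 6.32, 5.51, 7.83),
        "ne_pct": ("ln", 61.0, 55.6, 67.1),
        "ly_pct": ("ln", 27.5, 21.3, 32.3),
        "hb": ("ln", 142.0, 125.0, 154.0),
        "plt": ("ln", 215.0, 200.0, 248.0),
        "alb": ("tn", 32.31, 3.95, 12.0, 55.0),
        "crp": ("ln", 2.03, 0.75, 3.15),
        "tg": ("ln", 1.83, 1.16, 2.54),
        "chol": ("ln", 4.38, 3.95, 5.57),
        "glu": ("ln", 7.20, 5.27, 10.35),
        "bun": ("ln", 6.80, 4.92, 9.69),
        "ua": ("ln", 329.0, 280.0, 395.0),
        "scr": ("ln", 85.7, 68.0, 112.0),
        "egfr": ("tn", 80.10, 28.18, 30.0, 170.0),
        "proteinuria_24h": ("ln", 1.53, 0.62, 3.49),
        "p_male": 28 / 39,
        "p_hypertension": 24 / 39,
        "glomerular_probs": {1: 0.35, 2: 0.65},
        "ifta_probs": {0: 0.30, 1: 0.45, 2: 0.20, 3: 0.05},
    },
    "severe": {
        "age": ("ln", 52, 45, 60),
        "diabetes_duration": ("ln", 10.0, 5.0, 16.0),
        "bmi": ("ln", 24.66, 22.49, 26.88),
        "wbc": ("ln", 6.20, 5.30, 7.95),
        "ne_pct": ("ln", 60.3, 54.2, 67.85),
        "ly_pct": ("ln", 28.5, 21.7, 33.58),
        "hb": ("ln", 122.5, 105.0, 135.0),
        "plt": ("ln", 246.0, 204.25, 281.50),
        "alb": ("tn", 30.43, 5.83, 12.0, 55.0),
        "crp": ("ln", 2.10, 1.28, 3.12),
        "tg": ("ln", 1.57, 1.10, 2.22),
        "chol": ("ln", 5.11, 4.24, 6.05),
        "glu": ("ln", 6.63, 4.85, 9.32),
        "bun": ("ln", 7.78, 5.91, 10.56),
        "ua": ("ln", 344.0, 292.0, 400.0),
        "scr": ("ln", 110.75, 78.03, 152.95),
        "egfr": ("tn", 66.87, 34.45, 30.0, 170.0),
        "proteinuria_24h": ("ln", 4.08, 2.17, 5.83),
        "p_male": 112 / 156,
        "p_hypertension": 114 / 156,
        "glomerular_probs": {3: 0.55, 4: 0.45},
        "ifta_probs": {0: 0.02, 1: 0.13, 2: 0.45, 3: 0.40},
    },
}

# z-score of the 75th percentile of the standard normal
_Z75 = stats.norm.ppf(0.75)

_ROUNDING = {
    "bmi": 2, "wbc": 2, "ne_pct": 1, "ly_pct": 1, "hb": 1, "plt": 1,
    "alb": 2, "crp": 2, "tg": 2, "chol": 2, "glu": 2, "bun": 2, "ua": 1,
    "scr": 2, "egfr": 2, "proteinuria_24h": 2, "diabetes_duration": 1,
}


def _sample_lab(spec: tuple, n: int, rng: np.random.Generator) -> np.ndarray:
    kind = spec[0]
    if kind == "ln":
        _, med, q1, q3 = spec
        mu = math.log(med)
        sigma = (math.log(q3) - math.log(q1)) / (2.0 * _Z75)
        return np.exp(rng.normal(mu, sigma, size=n))
    _, mean, sd, lo, hi = spec
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def _stratum_counts(n: int, proportions: Sequence[float]) -> list[int]:
    """Largest-remainder allocation so counts are deterministic and sum to n."""
    raw = [n * p for p in proportions]
    counts = [int(math.floor(r)) for r in raw]
    remainders = sorted(range(len(raw)), key=lambda i: raw[i] - counts[i], reverse=True)
    for i in remainders[: n - sum(counts)]:
        counts[i] += 1
    return counts


def generate_cohort(
    n: int,
    seed: int,
    severity_mix: Sequence[float] = (39 / 195, 156 / 195),
) -> list[PatientRecord]:
    """Generate a synthetic biopsy cohort of ``n`` patients.

    ``severity_mix`` gives the (mild, severe) glomerular-stratum proportions;
    the default is the 39/156 split of the emulated cohort.  Deterministic
    given ``seed``.
    """
    if n < 10:
        raise ConfigError(f"cohort size must be >= 10, got {n}")
    mix = list(severity_mix)
    if len(mix) != 2 or any(p < 0 for p in mix) or abs(sum(mix) - 1.0) > 1e-9:
        raise ConfigError(f"severity_mix must be two nonnegative proportions summing to 1, got {severity_mix}")

    rng = np.random.default_rng(seed)
    counts = _stratum_counts(n, mix)
    records: list[PatientRecord] = []
    pid = 0
    for stratum, n_s in zip(("mild", "severe"), counts):
        if n_s == 0:
            continue
        params = _STRATUM_PARAMS[stratum]
        labs = {}
        for name, spec in params.items():
            if isinstance(spec, tuple):
                labs[name] = _sample_lab(spec, n_s, rng)
        sex = np.where(rng.random(n_s) < params["p_male"], "male", "female")
        htn = rng.random(n_s) < params["p_hypertension"]
        g_classes = rng.choice(
            list(params["glomerular_probs"]), size=n_s, p=list(params["glomerular_probs"].values())
        )
        ifta = rng.choice(
            list(params["ifta_probs"]), size=n_s, p=list(params["ifta_probs"].values())
        )
        # keep the differential plausible: neutrophil% + lymphocyte% <= 100
        ne = np.clip(labs["ne_pct"], 1.0, 98.0)
        ly = np.clip(labs["ly_pct"], 1.0, 100.0 - ne)
        egfr = np.maximum(labs["egfr"], 30.0)
        for i in range(n_s):
            pid += 1
            plt_v = round(float(labs["plt"][i]), _ROUNDING["plt"])
            alb_v = round(float(labs["alb"][i]), _ROUNDING["alb"])
            rec = PatientRecord(
                id=f"SYN{pid:04d}",
                age=int(np.clip(round(labs["age"][i]), 18, 90)),
                sex=str(sex[i]),
                diabetes_duration=round(float(np.clip(labs["diabetes_duration"][i], 0.5, 45.0)), 1),
                hypertension=bool(htn[i]),
                bmi=round(float(labs["bmi"][i]), 2),
                wbc=round(float(labs["wbc"][i]), 2),
                ne_pct=round(float(ne[i]), 1),
                ly_pct=round(float(ly[i]), 1),
                hb=round(float(labs["hb"][i]), 1),
                plt=plt_v,
                alb=alb_v,
                crp=round(float(labs["crp"][i]), 2),
                tg=round(float(labs["tg"][i]), 2),
                chol=round(float(labs["chol"][i]), 2),
                glu=round(float(labs["glu"][i]), 2),
                bun=round(float(labs["bun"][i]), 2),
                ua=round(float(labs["ua"][i]), 1),
                scr=round(float(labs["scr"][i]), 2),
                egfr=round(float(egfr[i]), 2),
                proteinuria_24h=round(float(labs["proteinuria_24h"][i]), 2),
                par=round(derive_par(plt_v, alb_v), 3),
                glomerular_class=int(g_classes[i]),
                ifta_score=int(ifta[i]),
            )
            records.append(rec.validate())
    return records


# ---------------------------------------------------------------------------
# CSV I/O (complete-case contract: missing values are rejected, not imputed)
# ---------------------------------------------------------------------------

def cohort_to_frame(records: Iterable[PatientRecord]) -> pd.DataFrame:
    rows = [dataclasses.asdict(r) for r in records]
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def write_cohort(records: Sequence[PatientRecord], path) -> None:
    cohort_to_frame(records).to_csv(path, index=False)


def read_cohort(path) -> list[PatientRecord]:
    """Read a cohort CSV, validating header and completeness.

    Rows with any missing value are rejected (complete-case contract); the
    error names every offending row and column.
    """
    df = pd.read_csv(path, dtype={"id": str, "sex": str})
    missing_cols = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ParseError(f"cohort CSV missing required column(s): {', '.join(missing_cols)}")
    bad = []
    for col in CSV_COLUMNS:
        for idx in df.index[df[col].isna()]:
            bad.append(f"row {idx + 2} column '{col}'")  # +2: header + 1-based
    if bad:
        raise ParseError("incomplete rows rejected (complete-case analysis): " + "; ".join(bad))

    records = []
    for idx, row in df.iterrows():
        try:
            rec = PatientRecord(
                id=str(row["id"]),
                age=int(row["age"]),
                sex=str(row["sex"]),
                diabetes_duration=float(row["diabetes_duration"]),
                hypertension=_parse_bool(row["hypertension"]),
                bmi=float(row["bmi"]),
                wbc=float(row["wbc"]),
                ne_pct=float(row["ne_pct"]),
                ly_pct=float(row["ly_pct"]),
                hb=float(row["hb"]),
                plt=float(row["plt"]),
                alb=float(row["alb"]),
                crp=float(row["crp"]),
                tg=float(row["tg"]),
                chol=float(row["chol"]),
                glu=float(row["glu"]),
                bun=float(row["bun"]),
                ua=float(row["ua"]),
                scr=float(row["scr"]),
                egfr=float(row["egfr"]),
                proteinuria_24h=float(row["proteinuria_24h"]),
                par=float(row["par"]),
                glomerular_class=int(row["glomerular_class"]),
                ifta_score=int(row["ifta_score"]),
            ).validate()
        except (ValueError, TypeError) as exc:
            raise ParseError(f"row {idx + 2}: {exc}") from exc
        records.append(rec)
    return records


def _parse_bool(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    s = str(value).strip().lower()
    if s in ("true", "1", "yes"):
        return True
    if s in ("false", "0", "no"):
        return False
    raise ValueError(f"cannot interpret {value!r} as boolean")
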