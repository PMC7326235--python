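"""Readers and writers for the tool's text formats.

All tabular data is UTF-8 CSV with comma delimiter and '.' decimal mark;
missing values are empty fields. Model and cutoff files are flat
``key = value`` text. Write-then-read round-trips are value-identical.
"""
from __future__ import annotations

import csv
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence, Union

from .cohort import Oophorectomy, ParticipantRecord, Regularity
from .membership import MuAParams, MuBParams
from .scoring import RASModel, ScoredRecord
from .validation import HormoneCutoffs

PathLike = Union[str, Path]

COHORT_COLUMNS = [
    "id", "age", "periods_last_12m", "regularity", "smoker_current",
    "oophorectomy", "exogenous_hormone_use", "pregnant", "breastfeeding",
    "irregular_unrelated_to_menopause", "fsh", "estradiol",
]

_BOOL_FIELDS = (
    "smoker_current", "exogenous_hormone_use", "pregnant",
    "breastfeeding", "irregular_unrelated_to_menopause",
)


class FormatError(ValueError):
    """Malformed input file; the message names the row/column."""


def _parse_bool(value: str, row: int, column: str) -> bool:
    if value == "0":
        return False
    if value == "1":
        return True
    raise FormatError(f"row {row}, column {column}: expected 0 or 1, got {value!r}")


def read_cohort_csv(path: PathLike) -> list[ParticipantRecord]:
    """Read participant records from the cohort CSV schema."""
    records: list[ParticipantRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != COHORT_COLUMNS:
            raise FormatError(
                f"{path}: expected header {COHORT_COLUMNS}, got {reader.fieldnames}"
            )
        for i, row in enumerate(reader, start=2):
            try:
                regularity = Regularity(row["regularity"])
            except ValueError:
                raise FormatError(
                    f"row {i}, column regularity: unknown value {row['regularity']!r}"
                ) from None
            try:
                oophorectomy = Oophorectomy(row["oophorectomy"])
            except ValueError:
                raise FormatError(
                    f"row {i}, column oophorectomy: unknown value {row['oophorectomy']!r}"
                ) from None
            try:
                age = int(row["age"])
                periods = int(row["periods_last_12m"])
            except ValueError as exc:
                raise FormatError(f"row {i}: bad integer field ({exc})") from None
            bools = {f: _parse_bool(row[f], i, f) for f in _BOOL_FIELDS}

            def opt_float(col: str) -> Optional[float]:
                raw = row[col]
                if raw == "":
                    return None
                try:
                    return float(raw)
                except ValueError:
                    raise FormatError(
                        f"row {i}, column {col}: bad number {raw!r}"
                    ) from None

            records.append(
                ParticipantRecord(
                    id=row["id"],
                    age=age,
                    periods_last_12m=periods,
                    regularity=regularity,
                    oophorectomy=oophorectomy,
                    fsh=opt_float("fsh"),
                    estradiol=opt_float("estradiol"),
                    **bools,
                )
            )
    return records


def write_cohort_csv(records: Sequence[ParticipantRecord], path: PathLike) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(COHORT_COLUMNS)
        for r in records:
            writer.writerow([
                r.id, r.age, r.periods_last_12m, r.regularity.value,
                int(r.smoker_current), r.oophorectomy.value,
                int(r.exogenous_hormone_use), int(r.pregnant),
                int(r.breastfeeding), int(r.irregular_unrelated_to_menopause),
                "" if r.fsh is None else repr(r.fsh),
                "" if r.estradiol is None else repr(r.estradiol),
            ])


SCORED_COLUMNS = ["id", "ras", "mu_a", "mu_b", "m_age", "excluded_reason"]


def write_scored_csv(scored: Sequence[ScoredRecord], path: PathLike) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(SCORED_COLUMNS)
        for s in scored:
            writer.writerow([
                s.id,
                "" if s.ras is None else repr(s.ras),
                "" if s.mu_a_value is None else repr(s.mu_a_value),
                "" if s.mu_b_value is None else repr(s.mu_b_value),
                "" if s.m_age is None else repr(s.m_age),
                ";".join(r.value for r in s.excluded_reasons),
            ])


# ---------------------------------------------------------------------------
# key = value config files (model parameters, hormone cutoffs)

def _read_kv(path: PathLike) -> dict[str, str]:
    out: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise FormatError(f"{path}:{lineno}: expected 'key = value'")
        key, _, value = line.partition("=")
        out[key.strip()] = value.strip()
    return out


_MODEL_KEYS = (
    "mu_a.shift", "mu_a.c4", "mu_a.c3", "mu_a.c2", "mu_a.c1", "mu_a.c0",
    "mu_b.b2", "mu_b.b1", "mu_b.b0",
    "smoking_offset", "unilateral_oophorectomy_offset", "modifiers_enabled",
)


def read_model(path: PathLike) -> RASModel:
    """Read a scoring model from a ``key = value`` parameter file.

    Unknown keys are rejected with the offending key named.
    """
    kv = _read_kv(path)
    unknown = set(kv) - set(_MODEL_KEYS)
    if unknown:
        raise FormatError(f"{path}: unknown keys {sorted(unknown)}")
    missing = [k for k in _MODEL_KEYS if k not in kv and k != "modifiers_enabled"]
    if missing:
        raise FormatError(f"{path}: missing keys {missing}")
    f = lambda k: float(kv[k])
    return RASModel(
        mu_a=MuAParams(
            shift=f("mu_a.shift"), c4=f("mu_a.c4"), c3=f("mu_a.c3"),
            c2=f("mu_a.c2"), c1=f("mu_a.c1"), c0=f("mu_a.c0"),
        ),
        mu_b=MuBParams(b2=f("mu_b.b2"), b1=f("mu_b.b1"), b0=f("mu_b.b0")),
        smoking_offset=f("smoking_offset"),
        unilateral_oophorectomy_offset=f("unilateral_oophorectomy_offset"),
        modifiers_enabled=kv.get("modifiers_enabled", "1") == "1",
    )


def write_model(model: RASModel, path: PathLike) -> None:
    lines = [
        "# reproductive ageing score model parameters",
        f"mu_a.shift = {model.mu_a.shift!r}",
        f"mu_a.c4 = {model.mu_a.c4!r}",
        f"mu_a.c3 = {model.mu_a.c3!r}",
        f"mu_a.c2 = {model.mu_a.c2!r}",
        f"mu_a.c1 = {model.mu_a.c1!r}",
        f"mu_a.c0 = {model.mu_a.c0!r}",
        f"mu_b.b2 = {model.mu_b.b2!r}",
        f"mu_b.b1 = {model.mu_b.b1!r}",
        f"mu_b.b0 = {model.mu_b.b0!r}",
        f"smoking_offset = {model.smoking_offset!r}",
        f"unilateral_oophorectomy_offset = {model.unilateral_oophorectomy_offset!r}",
        f"modifiers_enabled = {int(model.modifiers_enabled)}",
    ]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


_CUTOFF_KEYS = ("fsh_nonmeno_max", "e2_nonmeno_min", "fsh_postmeno_min", "e2_postmeno_max")


def read_cutoffs(path: PathLike) -> HormoneCutoffs:
    kv = _read_kv(path)
    unknown = set(kv) - set(_CUTOFF_KEYS)
    if unknown:
        raise FormatError(f"{path}: unknown keys {sorted(unknown)}")
    return HormoneCutoffs(**{k: float(v) for k, v in kv.items()})


def load_published_model() -> RASModel:
    """The packaged default model with the published coefficients."""
    ref = resources.files("rascore.data").joinpath("published_model.cfg")
    with resources.as_file(ref) as path:
        return read_model(path)
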