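"""Transform raw ethnographic codes into analysis-ready occurrence variables.

Ethnographers code each variable per society on an ordinal scale:

* ``0`` — absent (there was enough information to judge the trait absent),
* ``1`` — present but rare,
* ``2`` — present, frequency unknown,
* ``3`` — present and common,
* ``NA`` — not enough information to code the variable either way.

For analysis the ordinal scale is collapsed to simple *occurrence*
(absent / present / missing).  On top of the collapsed codes this module

* merges the two carrying roles (pack animal, sled pulling) into a single
  ``carry`` function,
* builds the three any-of composite relationship dimensions (positive care,
  negative treatment, personhood — with missing personhood components
  equated to absent),
* counts the number of roles dogs fill per society, and
* filters societies by completeness rules.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Occurrence",
    "CodingError",
    "MAIN_FUNCTIONS",
    "DEFAULT_DIMENSIONS",
    "collapse_code",
    "merge_carry",
    "composite_dimension",
    "count_functions",
    "code_table",
    "filter_societies",
    "count_report",
    "load_dimension_config",
]


class Occurrence(str, enum.Enum):
    """Collapsed occurrence state of an ethnographic variable."""

    ABSENT = "absent"
    PRESENT = "present"
    MISSING = "missing"


class CodingError(ValueError):
    """Raised when a raw code is outside the 0/1/2/3/NA alphabet."""


#: The five main dog functions used in all downstream analyses.
MAIN_FUNCTIONS = ("hunting", "defence", "guarding_herds", "herding", "carry")

#: Raw CSV columns backing each main function.  ``carry`` is the merge of
#: the pack-animal and sled-pulling variables.
FUNCTION_COLUMNS: Mapping[str, tuple[str, ...]] = {
    "hunting": ("fn_hunting",),
    "defence": ("fn_defence",),
    "guarding_herds": ("fn_guarding_herds",),
    "herding": ("fn_herding",),
    "carry": ("fn_pack", "fn_sled"),
}

#: Component variables of the three relationship dimensions, and whether a
#: missing component is equated to absent (personhood only: in essentially
#: all societies an absence of recorded naming/mourning/kin treatment is
#: best read as absence of the behaviour).
DEFAULT_DIMENSIONS: Mapping[str, dict] = {
    "positive_care": {
        "columns": [
            "pc_fed_human_food",
            "pc_breastfed",
            "pc_sleep_indoors",
            "pc_allowed_indoors",
            "pc_groomed",
            "pc_played_with",
            "pc_trained",
            "pc_puppy_care",
            "pc_healthcare",
            "pc_equipment",
        ],
        "na_means_absent": False,
    },
    "negative_treatment": {
        "columns": [
            "nt_not_fed",
            "nt_no_healthcare",
            "nt_abused",
            "nt_culled",
            "nt_killed_disagreement",
            "nt_killed_aggression",
        ],
        "na_means_absent": False,
    },
    "personhood": {
        "columns": [
            "ph_named",
            "ph_talked_to",
            "ph_buried",
            "ph_mourned",
            "ph_kin",
        ],
        "na_means_absent": True,
    },
}

_MISSING_MARKERS = {None, "", "NA", "na", "NaN", "nan"}


def _is_missing(raw) -> bool:
    if raw is None:
        return True
    if isinstance(raw, float) and np.isnan(raw):
        return True
    if isinstance(raw, str) and raw.strip() in _MISSING_MARKERS:
        return True
    return False


def collapse_code(raw, *, society: str | None = None, variable: str | None = None) -> Occurrence:
    """Collapse a raw ordinal code into occurrence.

    0 maps to absent; 1, 2 and 3 (rare / unknown frequency / common) all map
    to present; a missing marker (None, NaN, empty string, "NA") stays
    missing.  Any other value raises :class:`CodingError` naming the society
    and variable when given.
    """
    if _is_missing(raw):
        return Occurrence.MISSING
    try:
        value = float(raw)
    except (TypeError, ValueError):
        value = None
    if value is None or value != int(value) or int(value) not in (0, 1, 2, 3):
        where = ""
        if society is not None or variable is not None:
            where = f" (society={society!r}, variable={variable!r})"
        raise CodingError(f"invalid raw code {raw!r}, expected 0/1/2/3/NA{where}")
    return Occurrence.ABSENT if int(value) == 0 else Occurrence.PRESENT


def merge_carry(pack: Occurrence, sled: Occurrence) -> Occurrence:
    """Merge the pack-animal and sled-pulling codes into one carry function.

    Present if either role is present; missing only if both are missing;
    absent otherwise (including the one-absent/one-missing case, where one
    carrying role is affirmatively absent).  Symmetric in its arguments.
    """
    if Occurrence.PRESENT in (pack, sled):
        return Occurrence.PRESENT
    if pack is Occurrence.MISSING and sled is Occurrence.MISSING:
        return Occurrence.MISSING
    return Occurrence.ABSENT


def composite_dimension(
    components: Sequence[Occurrence], *, na_means_absent: bool = False
) -> Occurrence:
    """Any-of composite over component occurrence codes.

    Present if any component is present.  With ``na_means_absent`` (the
    personhood rule) missing components count as absent, so the result is
    never missing.  Otherwise the composite is missing only when every
    component is missing: a single affirmative absence is enough information
    to score the dimension absent.
    """
    components = list(components)
    if not components:
        raise ValueError("composite_dimension requires at least one component")
    if Occurrence.PRESENT in components:
        return Occurrence.PRESENT
    if na_means_absent:
        return Occurrence.ABSENT
    if all(c is Occurrence.MISSING for c in components):
        return Occurrence.MISSING
    return Occurrence.ABSENT


def count_functions(profile: Mapping[str, Occurrence]):
    """Number of present main functions, or None if any main is missing."""
    codes = [profile[f] for f in MAIN_FUNCTIONS]
    if any(c is Occurrence.MISSING for c in codes):
        return None
    return sum(c is Occurrence.PRESENT for c in codes)


def load_dimension_config(path) -> Mapping[str, dict]:
    """Load dimension component lists from YAML; shape as DEFAULT_DIMENSIONS."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    dims = cfg.get("dimensions", cfg)
    out = {}
    for name, spec in dims.items():
        if not isinstance(spec, dict) or "columns" not in spec:
            raise ValueError(f"dimension {name!r} must map to {{columns: [...], na_means_absent: bool}}")
        out[name] = {
            "columns": list(spec["columns"]),
            "na_means_absent": bool(spec.get("na_means_absent", False)),
        }
    return out


def _collapse_column(df: pd.DataFrame, col: str) -> list[Occurrence]:
    out = []
    for sid, raw in zip(df["society_id"], df[col]):
        out.append(collapse_code(raw, society=str(sid), variable=col))
    return out


def code_table(
    df: pd.DataFrame, dimensions: Mapping[str, dict] | None = None
) -> pd.DataFrame:
    """Collapse a raw society table into occurrence codes and derived columns.

    Returns a new frame indexed like ``df`` with one occurrence column per
    main function (carry merged), one per relationship dimension, and
    ``n_functions`` (nullable integer; defined only when all five mains are
    non-missing).  Passthrough columns (ids, coordinates, covariates) are
    retained.  Deterministic: coding the same table twice gives identical
    output.
    """
    if dimensions is None:
        dimensions = DEFAULT_DIMENSIONS
    if "society_id" not in df.columns:
        raise CodingError("input table must have a society_id column")

    out = pd.DataFrame(index=df.index)
    carry_cols = set(df.columns)
    for fn, cols in FUNCTION_COLUMNS.items():
        missing_cols = [c for c in cols if c not in df.columns]
        if missing_cols:
            raise CodingError(f"missing raw columns for function {fn!r}: {missing_cols}")
        collapsed = [_collapse_column(df, c) for c in cols]
        if len(collapsed) == 1:
            out[fn] = [c.value for c in collapsed[0]]
        else:
            out[fn] = [merge_carry(a, b).value for a, b in zip(*collapsed)]
        carry_cols -= set(cols)

    for dim, spec in dimensions.items():
        missing_cols = [c for c in spec["columns"] if c not in df.columns]
        if missing_cols:
            raise CodingError(f"missing raw columns for dimension {dim!r}: {missing_cols}")
        collapsed = [_collapse_column(df, c) for c in spec["columns"]]
        out[dim] = [
            composite_dimension(row, na_means_absent=spec["na_means_absent"]).value
            for row in zip(*collapsed)
        ]
        carry_cols -= set(spec["columns"])

    n_fn = []
    for _, row in out.iterrows():
        profile = {f: Occurrence(row[f]) for f in MAIN_FUNCTIONS}
        n_fn.append(count_functions(profile))
    out["n_functions"] = pd.array(n_fn, dtype="Int64")

    passthrough = [c for c in df.columns if c in carry_cols]
    return pd.concat([df[passthrough].reset_index(drop=True),
                      out.reset_index(drop=True)], axis=1)


FILTER_RULES = ("any_main_non_missing", "all_mains_non_missing", "full_dimensions")


def filter_societies(coded: pd.DataFrame, rule: str) -> pd.DataFrame:
    """Subset a coded table by a completeness rule.  Idempotent.

    ``any_main_non_missing``: at least one of the five main functions coded.
    ``all_mains_non_missing``: all five mains coded (n_functions defined).
    ``full_dimensions``: every relationship dimension non-missing.
    """
    miss = Occurrence.MISSING.value
    mains = coded[list(MAIN_FUNCTIONS)]
    if rule == "any_main_non_missing":
        keep = (mains != miss).any(axis=1)
    elif rule == "all_mains_non_missing":
        keep = (mains != miss).all(axis=1)
    elif rule == "full_dimensions":
        dims = [c for c in ("positive_care", "negative_treatment", "personhood") if c in coded]
        keep = (coded[dims] != miss).all(axis=1)
    else:
        raise ValueError(f"unknown filter rule {rule!r}; expected one of {FILTER_RULES}")
    return coded.loc[keep]


def count_report(coded: pd.DataFrame) -> dict:
    """Society counts summarising a coded table.

    The single/multi/zero-function split counts *present* codes among
    societies with at least one coded main (a missing main simply cannot
    contribute a presence); n_functions proper is reserved for societies
    with all five mains coded.
    """
    miss = Occurrence.MISSING.value
    pres = Occurrence.PRESENT.value
    any_main = filter_societies(coded, "any_main_non_missing")
    all_mains = filter_societies(coded, "all_mains_non_missing")
    full_dims = filter_societies(coded, "full_dimensions")

    n_present = (any_main[list(MAIN_FUNCTIONS)] == pres).sum(axis=1)
    both = (
        (full_dims["positive_care"] == pres) & (full_dims["negative_treatment"] == pres)
    )
    all_three = both & (full_dims["personhood"] == pres)

    report = {
        "n_societies": int(len(coded)),
        "any_main_non_missing": int(len(any_main)),
        "all_mains_non_missing": int(len(all_mains)),
        "zero_function": int((n_present == 0).sum()),
        "single_function": int((n_present == 1).sum()),
        "multi_function": int((n_present >= 2).sum()),
        "function_presence": {
            f: int((any_main[f] == pres).sum()) for f in MAIN_FUNCTIONS
        },
        "full_dimensions": int(len(full_dims)),
        "positive_and_negative_present": int(both.sum()),
        "all_three_present": int(all_three.sum()),
    }
    return report
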