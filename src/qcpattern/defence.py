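"""Chemical-defence categorisation from shrimp assay values.

Species are scored with unpalatability (1 − ED50, feeding-rejection assays)
and toxicity (1 − LD50, brine-shrimp assays), both oriented so 0 = fully
palatable/non-toxic and 1 = maximally defended, and binned into three classes:

* ``undefended``      : 1 − LD50 = 0 and 1 − ED50 = 0
* ``toxic_moderate``  : 1 − LD50 > 0 and 0.25 < 1 − ED50 <= 0.74
* ``toxic_high``      : 1 − LD50 > 0 and 1 − ED50 > 0.74

The 0.74 cut is the median unpalatability of defended species in the source
assay set (close to the inflexion of a sigmoidal dose-response) and is kept as
a fixed constant by default; both boundaries are closed on the moderate side.
"not rejected" (NR) assay outcomes count as 0, and multiple whole-body
extracts per species are arithmetically averaged before classification.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

DEFENCE_LEVELS = ("undefended", "toxic_moderate", "toxic_high")
ED50_MODERATE_FLOOR = 0.25
ED50_HIGH_THRESHOLD = 0.74


class UnclassifiableError(ValueError):
    """Assay combination outside the three defined defence regions."""


@dataclass
class AssayRecord:
    species: str
    one_minus_ed50: float  # may be "NR" before resolution
    one_minus_ld50: float
    n_extracts: int = 1


def _resolve_nr(v):
    if isinstance(v, str):
        if v.strip().upper() == "NR":
            return 0.0
        return float(v)
    return float(v)


def resolve_assays(records: Sequence[AssayRecord]) -> AssayRecord:
    """Collapse multiple extracts of one species into a single assay record.

    NR values are set to 0 before arithmetic averaging. Only whole-body
    extracts should be passed (the caller filters extract types).
    """
    records = list(records)
    if not records:
        raise ValueError("no assay records supplied")
    sp = {r.species for r in records}
    if len(sp) > 1:
        raise ValueError(f"records span multiple species: {sorted(sp)}")
    ed = float(np.mean([_resolve_nr(r.one_minus_ed50) for r in records]))
    ld = float(np.mean([_resolve_nr(r.one_minus_ld50) for r in records]))
    for v in (ed, ld):
        if not 0.0 <= v <= 1.0:
            raise ValueError("assay values must lie in [0, 1] after NR resolution")
    return AssayRecord(records[0].species, ed, ld, n_extracts=len(records))


def impute_from_sisters(records: Iterable[AssayRecord]) -> AssayRecord:
    """Assay record for a species lacking assays, averaged from named sister species."""
    records = [resolve_assays([r]) for r in records]
    if len(records) < 2:
        raise ValueError("sister-species imputation needs >= 2 relatives")
    return AssayRecord(
        species="",
        one_minus_ed50=float(np.mean([r.one_minus_ed50 for r in records])),
        one_minus_ld50=float(np.mean([r.one_minus_ld50 for r in records])),
        n_extracts=0,
    )


def classify(ed: float, ld: float, high_threshold: float = ED50_HIGH_THRESHOLD) -> str:
    """Assign a resolved (1−ED50, 1−LD50) pair to one of the three defence classes."""
    if not (0.0 <= ed <= 1.0 and 0.0 <= ld <= 1.0):
        raise ValueError("ed and ld must lie in [0, 1]")
    if ld == 0 and ed == 0:
        return "undefended"
    if ld > 0 and ED50_MODERATE_FLOOR < ed <= high_threshold:
        return "toxic_moderate"
    if ld > 0 and ed > high_threshold:
        return "toxic_high"
    raise UnclassifiableError(
        f"assay combination (1-ED50={ed}, 1-LD50={ld}) matches no defence class"
    )


def classify_table(df: pd.DataFrame, recompute_threshold: bool = False) -> pd.DataFrame:
    """Resolve and classify an assay table (columns: species, one_minus_ed50,
    one_minus_ld50, optional extract_type restricted to whole-body upstream).

    With ``recompute_threshold`` the moderate/high cut is re-derived as the
    median 1−ED50 of defended species instead of the fixed 0.74 constant.
    """
    rows = []
    for sp, grp in df.groupby("species", sort=True):
        recs = [AssayRecord(sp, r.one_minus_ed50, r.one_minus_ld50)
                for r in grp.itertuples()]
        rows.append(resolve_assays(recs))
    thr = ED50_HIGH_THRESHOLD
    if recompute_threshold:
        defended = [r.one_minus_ed50 for r in rows
                    if not (r.one_minus_ed50 == 0 and r.one_minus_ld50 == 0)]
        thr = float(np.median(defended))
    return pd.DataFrame({
        "species": [r.species for r in rows],
        "one_minus_ed50": [r.one_minus_ed50 for r in rows],
        "one_minus_ld50": [r.one_minus_ld50 for r in rows],
        "n_extracts": [r.n_extracts for r in rows],
        "defence": [classify(r.one_minus_ed50, r.one_minus_ld50, thr) for r in rows],
    })
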