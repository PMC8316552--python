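"""TEM vacuole classification rule and per-cell morphometry.

A vacuole below the diameter gate (default 0.5 µm) is excluded.  Above
the gate it is an autophagosome (APG) when two or more of the four APG
criteria hold; otherwise an autolysosome (AUT) when at least one AUT
criterion holds; otherwise unclassified.  APG takes precedence, so no
vacuole is double-counted.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import InputError
from .scene_sim import APG_CRITERIA, AUT_CRITERIA

logger = logging.getLogger(__name__)

__all__ = ["classify_vacuole", "classify_table", "morphometry_summary",
           "APG_CRITERIA", "AUT_CRITERIA"]

DEFAULT_SIZE_GATE_UM = 0.5


def classify_vacuole(
    annotation: dict | pd.Series, size_gate: float = DEFAULT_SIZE_GATE_UM
) -> str:
    """Assign APG / AUT / excluded / unclassified to one vacuole.

    ``annotation`` must carry ``diameter_um`` and all seven criterion
    booleans.  A pure function of (criteria, diameter).
    """
    for f in ("diameter_um",) + APG_CRITERIA + AUT_CRITERIA:
        if f not in annotation:
            raise InputError(f"missing vacuole annotation field {f!r}")
    if annotation["diameter_um"] < size_gate:
        return "excluded"
    n_apg = sum(bool(annotation[c]) for c in APG_CRITERIA)
    if n_apg >= 2:
        return "APG"
    if any(bool(annotation[c]) for c in AUT_CRITERIA):
        return "AUT"
    return "unclassified"


def classify_table(
    vacuoles: pd.DataFrame, size_gate: float = DEFAULT_SIZE_GATE_UM
) -> pd.DataFrame:
    """Return a copy of the table with an assigned ``class`` column."""
    out = vacuoles.copy()
    out["class"] = [
        classify_vacuole(row, size_gate=size_gate) for _, row in out.iterrows()
    ]
    n_un = int((out["class"] == "unclassified").sum())
    if n_un:
        logger.warning("%d vacuole(s) matched neither rule (unclassified)", n_un)
    return out


def morphometry_summary(
    vacuoles: pd.DataFrame, cell_areas: pd.DataFrame
) -> pd.DataFrame:
    """Per-cell counts, maturation percentages and area statistics.

    ``vacuoles`` needs columns cell, area_um2, class; ``cell_areas``
    needs columns cell, cell_area_um2.  Excluded/unclassified vacuoles
    do not enter AV.  Output columns: AV, APG, AUT counts, AV area
    fraction of the cell, mean APG/AUT areas and the %APG / %AUT split.
    """
    if "class" not in vacuoles.columns:
        raise InputError("vacuole table has no 'class' column; classify first")
    areas = cell_areas.set_index("cell")["cell_area_um2"]
    unknown = set(vacuoles["cell"]) - set(areas.index)
    if unknown:
        raise InputError(f"no cell area for cell id(s): {sorted(unknown)}")
    rows = []
    for cell, grp in vacuoles.groupby("cell", sort=True):
        apg = grp[grp["class"] == "APG"]
        aut = grp[grp["class"] == "AUT"]
        av = len(apg) + len(aut)
        av_area = apg["area_um2"].sum() + aut["area_um2"].sum()
        rows.append(
            {
                "cell": cell,
                "AV": av,
                "APG": len(apg),
                "AUT": len(aut),
                "av_area_fraction": av_area / areas[cell],
                "mean_apg_area_um2": apg["area_um2"].mean() if len(apg) else np.nan,
                "mean_aut_area_um2": aut["area_um2"].mean() if len(aut) else np.nan,
                "pct_APG": 100.0 * len(apg) / av if av else np.nan,
                "pct_AUT": 100.0 * len(aut) / av if av else np.nan,
                "n_excluded": int((grp["class"] == "excluded").sum()),
                "n_unclassified": int((grp["class"] == "unclassified").sum()),
            }
        )
    return pd.DataFrame(rows)
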