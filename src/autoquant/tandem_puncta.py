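"""Punctum detection and tandem-reporter (red/green) flux scoring.

Red (mCherry) puncta count all autophagic vacuoles (AV); red puncta
with a coincident green (GFP) punctum are autophagosomes (APG); red-only
puncta are autolysosomes (AL), the flux readout.  AV = APG + AL always.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max

from .errors import ParameterError

logger = logging.getLogger(__name__)

__all__ = ["Punctum", "PunctaSummary", "detect_puncta", "classify_tandem", "summarize_flux"]


@dataclass(frozen=True)
class Punctum:
    """A detected spot: sub-pixel center, detection scale and peak response."""

    row: float
    col: float
    scale: float
    peak: float
    channel: str = ""


@dataclass
class PunctaSummary:
    """Per-cell AV / APG / AL counts.  Invariant: AV = APG + AL."""

    av: int
    apg: int
    al: int
    match_radius: float
    cell_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        if self.av != self.apg + self.al:
            raise ParameterError(
                f"AV ({self.av}) != APG ({self.apg}) + AL ({self.al})"
            )
        if min(self.av, self.apg, self.al) < 0:
            raise ParameterError("negative puncta count")


def _subpixel_refine(response: np.ndarray, r: int, c: int) -> tuple[float, float]:
    """One-step quadratic (parabolic) peak interpolation per axis."""
    out = [float(r), float(c)]
    for axis, idx in enumerate((r, c)):
        if idx <= 0 or idx >= response.shape[axis] - 1:
            continue
        if axis == 0:
            fm, f0, fp = response[r - 1, c], response[r, c], response[r + 1, c]
        else:
            fm, f0, fp = response[r, c - 1], response[r, c], response[r, c + 1]
        denom = fm - 2 * f0 + fp
        if denom < 0:
            shift = 0.5 * (fm - fp) / denom
            out[axis] += float(np.clip(shift, -0.5, 0.5))
    return out[0], out[1]


def detect_puncta(
    image: np.ndarray,
    sigma: float = 1.5,
    threshold_rel: float = 0.1,
    channel: str = "",
) -> list[Punctum]:
    """Detect puncta as local maxima of a Laplacian-of-Gaussian response.

    The response is the scale-normalized negative LoG at scale ``sigma``;
    maxima below ``threshold_rel`` times the maximum response are
    discarded, and maxima closer than ``2 * sigma`` keep only the
    strongest.  Centers are refined to sub-pixel accuracy by parabolic
    interpolation.
    """
    if sigma <= 0:
        raise ParameterError(f"sigma must be > 0, got {sigma}")
    if not 0 < threshold_rel <= 1:
        raise ParameterError(f"threshold must be in (0, 1], got {threshold_rel}")
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ParameterError("detect_puncta expects a 2-D image")
    response = -(sigma**2) * ndi.gaussian_laplace(image, sigma)
    max_resp = response.max()
    if max_resp <= 0:
        return []
    coords = peak_local_max(
        response,
        min_distance=max(1, int(np.ceil(2 * sigma))),
        threshold_abs=threshold_rel * max_resp,
        exclude_border=False,
    )
    puncta = []
    for r, c in coords:
        rr, cc = _subpixel_refine(response, int(r), int(c))
        puncta.append(
            Punctum(row=rr, col=cc, scale=sigma, peak=float(response[r, c]), channel=channel)
        )
    # deterministic order regardless of peak_local_max internals
    puncta.sort(key=lambda p: (p.row, p.col))
    return puncta


def classify_tandem(
    red: list[Punctum],
    green: list[Punctum],
    match_radius: float,
    cell_id: str = "",
    condition: str = "",
) -> PunctaSummary:
    """Score red puncta as APG (green-matched) or AL (red-only).

    Greedy nearest-pair matching: candidate pairs within the match
    radius are taken in increasing distance order, each red and each
    green punctum used at most once.  Inputs are sorted by (row, col)
    first so equidistant ties resolve deterministically.  Green-only
    puncta are ignored (their count is logged).
    """
    if match_radius <= 0:
        raise ParameterError(f"match radius must be > 0, got {match_radius}")
    red = sorted(red, key=lambda p: (p.row, p.col))
    green = sorted(green, key=lambda p: (p.row, p.col))
    n_apg = 0
    if red and green:
        r_pos = np.array([(p.row, p.col) for p in red])
        g_pos = np.array([(p.row, p.col) for p in green])
        d = np.sqrt(
            ((r_pos[:, None, :] - g_pos[None, :, :]) ** 2).sum(axis=2)
        )
        pairs = [
            (d[i, j], i, j)
            for i in range(len(red))
            for j in range(len(green))
            if d[i, j] <= match_radius
        ]
        pairs.sort()
        used_r: set[int] = set()
        used_g: set[int] = set()
        for _, i, j in pairs:
            if i in used_r or j in used_g:
                continue
            used_r.add(i)
            used_g.add(j)
            n_apg += 1
        unmatched_green = len(green) - len(used_g)
    else:
        unmatched_green = len(green)
    if unmatched_green:
        logger.info("%d green-only puncta ignored", unmatched_green)
    av = len(red)
    return PunctaSummary(
        av=av,
        apg=n_apg,
        al=av - n_apg,
        match_radius=match_radius,
        cell_id=cell_id,
        condition=condition,
    )


def summarize_flux(summaries: list[PunctaSummary]) -> pd.DataFrame:
    """Per-condition mean ± SEM of AV, APG, AL counts; flux = mean AL/cell."""
    if not summaries:
        raise ParameterError("no puncta summaries to aggregate")
    df = pd.DataFrame(
        {
            "condition": [s.condition for s in summaries],
            "cell": [s.cell_id for s in summaries],
            "AV": [s.av for s in summaries],
            "APG": [s.apg for s in summaries],
            "AL": [s.al for s in summaries],
        }
    )
    rows = []
    for cond, grp in df.groupby("condition", sort=True):
        n = len(grp)
        entry: dict = {"condition": cond, "n_cells": n}
        for count in ("AV", "APG", "AL"):
            vals = grp[count].to_numpy(dtype=float)
            entry[f"{count}_mean"] = vals.mean()
            entry[f"{count}_sem"] = (
                vals.std(ddof=1) / np.sqrt(n) if n > 1 else 0.0
            )
        entry["flux_AL_per_cell"] = entry["AL_mean"]
        rows.append(entry)
    return pd.DataFrame(rows)
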