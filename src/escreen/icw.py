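"""In-Cell Western intensity processing.

Turns raw two-channel well intensities into vehicle-relative responses on
the two endpoint axes the screen reads out:

* ``cell_number`` — channel-700 (cell stain) intensity relative to the
  plate's vehicle mean;
* ``differentiation`` — the per-well 800/700 ratio (myosin signal corrected
  for cell number) relative to the plate's vehicle-mean ratio.

Background is estimated per plate and channel from the no-stain control
wells; vehicle statistics are computed per plate. Duplicate wells are kept
as individual observations — the downstream ±2 SD activity rule and the
curve fitter both consume unaveraged replicate values.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .simulate import CELL_AXIS, DIFF_AXIS, NOSTAIN, VEHICLE

QC_OK = "ok"
QC_OUTLIER = "outlier"
QC_MISSING = "missing"

RESPONSE_COLUMNS = [
    "chemical", "conc_uM", "endpoint_axis", "replicate_id", "value", "qc_flag", "plate_id",
]


class ProcessingError(RuntimeError):
    """Raised when a plate cannot be processed (missing controls etc.)."""


def _ensure_qc(wells: pd.DataFrame) -> pd.DataFrame:
    wells = wells.copy()
    if "qc_flag" not in wells.columns:
        wells["qc_flag"] = QC_OK
    return wells


def background_correct(wells: pd.DataFrame) -> pd.DataFrame:
    """Subtract the per-plate mean no-stain intensity from each channel.

    Corrected intensities that would go negative are clamped to zero and the
    well is flagged as an outlier.
    """
    wells = _ensure_qc(wells)
    for plate_id, idx in wells.groupby("plate_id").groups.items():
        sub = wells.loc[idx]
        ns = sub[sub["chemical"] == NOSTAIN]
        if ns.empty:
            raise ProcessingError(f"plate {plate_id!r} has no no-stain background wells")
        for ch in ("channel700", "channel800"):
            corrected = sub[ch] - ns[ch].mean()
            neg = corrected < 0
            wells.loc[idx, ch] = corrected.clip(lower=0.0)
            flag_idx = sub.index[neg & (sub["chemical"] != NOSTAIN)]
            wells.loc[flag_idx, "qc_flag"] = QC_OUTLIER
    return wells


def differentiation_index(wells: pd.DataFrame) -> pd.Series:
    """Per-well 800/700 ratio; wells with zero channel 700 become NaN.

    Mutates the ``qc_flag`` column of ``wells`` in place to mark zero-cell
    wells as missing so they are excluded downstream.
    """
    zero = wells["channel700"] <= 0
    wells.loc[zero & (wells["chemical"] != NOSTAIN), "qc_flag"] = QC_MISSING
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = wells["channel800"] / wells["channel700"]
    return ratio.where(~zero)


def relative_to_vehicle(wells: pd.DataFrame) -> pd.DataFrame:
    """Vehicle-relative responses per well, long format over the two axes.

    Each plate is normalized to its own vehicle wells: channel 700 by the
    vehicle-mean intensity, the differentiation index by the vehicle-mean
    index. Vehicle wells themselves are emitted as 0-concentration records
    (their per-plate mean is exactly 1) so control variability is available
    downstream. No-stain wells are dropped.
    """
    wells = _ensure_qc(wells)
    wells = wells[wells["chemical"] != NOSTAIN].copy()
    wells["diff_index"] = differentiation_index(wells)

    records = []
    for plate_id, sub in wells.groupby("plate_id", sort=True):
        veh = sub[(sub["chemical"] == VEHICLE) & (sub["qc_flag"] == QC_OK)]
        if len(veh) < 2:
            raise ProcessingError(f"plate {plate_id!r} has fewer than 2 usable vehicle wells")
        v700 = veh["channel700"].mean()
        vratio = veh["diff_index"].mean()
        if not v700 > 0 or not vratio > 0:
            raise ProcessingError(f"plate {plate_id!r} vehicle mean is zero")
        for _, w in sub.iterrows():
            rep = f"{plate_id}:r{int(w['row'])}c{int(w['col'])}"
            records.append((w["chemical"], w["conc_uM"], CELL_AXIS, rep,
                            w["channel700"] / v700, w["qc_flag"], plate_id))
            flag = w["qc_flag"]
            value = w["diff_index"] / vratio
            if np.isnan(value) and flag == QC_OK:
                flag = QC_MISSING
            records.append((w["chemical"], w["conc_uM"], DIFF_AXIS, rep,
                            value, flag, plate_id))
    return pd.DataFrame(records, columns=RESPONSE_COLUMNS)


def process_screen(wells: pd.DataFrame) -> pd.DataFrame:
    """background_correct + relative_to_vehicle in one call."""
    return relative_to_vehicle(background_correct(wells))


def replicate_cv(values) -> float:
    """Coefficient of variation in percent: 100 * sample SD / mean.

    NaN when fewer than two values or when the mean is zero.
    """
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    if values.size < 2:
        return float("nan")
    mean = values.mean()
    if mean == 0:
        return float("nan")
    return float(100.0 * values.std(ddof=1) / mean)


def replicate_cv_table(responses: pd.DataFrame, chemicals=None) -> pd.DataFrame:
    """Replicate CV per chemical x concentration x axis over usable wells."""
    resp = responses[responses["qc_flag"] == QC_OK]
    if chemicals is not None:
        resp = resp[resp["chemical"].isin(chemicals)]
    rows = [
        (chem, conc, axis, len(grp), replicate_cv(grp["value"]))
        for (chem, conc, axis), grp in resp.groupby(["chemical", "conc_uM", "endpoint_axis"])
    ]
    return pd.DataFrame(rows, columns=["chemical", "conc_uM", "endpoint_axis", "n", "cv_pct"])


def qc_flag_outliers(responses: pd.DataFrame, k: float = 5.0, enabled: bool = False) -> pd.DataFrame:
    """Flag replicates deviating from their group median by more than k·MAD.

    An automated surrogate for manual plate-image inspection; disabled by
    default. Groups are chemical x concentration x axis.
    """
    if not enabled:
        return responses
    responses = responses.copy()
    for _, grp in responses.groupby(["chemical", "conc_uM", "endpoint_axis"]):
        ok = grp[grp["qc_flag"] == QC_OK]
        if len(ok) < 2:
            continue
        med = ok["value"].median()
        mad = (ok["value"] - med).abs().median()
        out = ok.index[(ok["value"] - med).abs() > k * mad]
        responses.loc[out, "qc_flag"] = QC_OUTLIER
    return responses


def read_responses(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"qc_flag": str})


def write_responses(responses: pd.DataFrame, path) -> None:
    responses.to_csv(path, index=False)
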