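"""Mitochondrial energetics: mitostress parameters and mtDNA content.

The extracellular-flux (mitostress) assay records oxygen consumption
rate (OCR) under sequential injections of oligomycin (ATP-synthase
inhibitor), FCCP (uncoupler), rotenone (complex-I inhibitor) and plain
assay medium, with three measurements per ~20-minute window.  Six
respiration parameters are derived from window averages; OCR is first
normalized to a fixed cell number (30,000 by default) so runs with
different seeding densities are comparable.

Relative mitochondrial DNA content is estimated from qPCR cycle
thresholds by the comparative-CT (delta-delta-CT) method using a
mitochondrial probe (MT-ND1 or MT-ND2) against a nuclear reference
(ACTB).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Protocol measurement windows in minutes, keyed by assay phase:
#: basal, post-oligomycin, post-FCCP, post-rotenone, post-medium.
DEFAULT_WINDOWS: dict[str, tuple[float, float]] = {
    "basal": (0.0, 15.0),
    "oligomycin": (20.0, 35.0),
    "fccp": (40.0, 55.0),
    "rotenone": (60.0, 75.0),
    "medium": (80.0, 95.0),
}

MITO_PROBES = ("MT-ND1", "MT-ND2")
NUCLEAR_PROBE = "ACTB"


@dataclass(frozen=True)
class InjectionPlan:
    """Port-injection dilution arithmetic for one compound."""

    stock_um: float
    injected_ul: float
    well_ul: float
    final_um: float
    dilution_factor: float


@dataclass
class OcrTrace:
    """One well's OCR time series.

    ``time_min`` strictly increasing; ``ocr`` in pmol O2/min for the
    well; ``cell_count`` from a nuclei count of the same well (protein
    normalization is avoided because hypertrophy raises protein/DNA).
    """

    time_min: np.ndarray
    ocr: np.ndarray
    cell_count: int
    well: str = "well"
    injections: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.ocr = np.asarray(self.ocr, dtype=float)
        if self.time_min.shape != self.ocr.shape:
            raise ValueError("time and OCR arrays must have the same length")
        if np.any(np.diff(self.time_min) <= 0):
            raise ValueError("timepoints must be strictly increasing")


@dataclass(frozen=True)
class MitoStressResult:
    """The six respiration parameters, pmol O2/min per normalization unit."""

    basal: float
    maximal: float
    atp_production: float
    spare_capacity: float
    non_mito: float
    proton_leak: float


def injection_concentration(stock_um: float, v_inj_ul: float,
                            v_well_ul: float) -> InjectionPlan:
    """Final in-well concentration and dilution factor for a port injection.

    final = stock * v_inj / (v_inj + v_well); dilution = (v_inj + v_well)/v_inj.
    E.g. 12 uM oligomycin injected at 25 uL into 175 uL gives 1.5 uM (8X).
    """
    if stock_um <= 0 or v_inj_ul <= 0 or v_well_ul <= 0:
        raise ValueError("stock, injected and well volumes must all be > 0")
    total = v_inj_ul + v_well_ul
    return InjectionPlan(stock_um=stock_um, injected_ul=v_inj_ul,
                         well_ul=v_well_ul,
                         final_um=stock_um * v_inj_ul / total,
                         dilution_factor=total / v_inj_ul)


def normalize_ocr(trace: OcrTrace, per_cells: int = 30_000) -> OcrTrace:
    """Rescale OCR to a fixed cell number (default per 30,000 cells)."""
    if trace.cell_count <= 0:
        raise ValueError("cell count must be > 0 to normalize")
    factor = per_cells / trace.cell_count
    return replace(trace, ocr=trace.ocr * factor, cell_count=per_cells)


def _window_average(trace: OcrTrace, window: tuple[float, float],
                    name: str) -> float:
    lo, hi = window
    mask = (trace.time_min >= lo) & (trace.time_min <= hi)
    if not mask.any():
        raise ValueError(
            f"no OCR measurements in the {name} window [{lo}-{hi} min]")
    return float(trace.ocr[mask].mean())


def mitostress_parameters(
    trace: OcrTrace,
    windows: dict[str, tuple[float, float]] | None = None,
    single_non_mito_window: bool = False,
) -> MitoStressResult:
    """Derive the six mitostress respiration parameters.

    With window averages A_basal .. A_medium over the five phases::

        basal        = A_basal    - A_medium
        maximal      = A_fccp     - A_rotenone
        atp          = A_basal    - A_oligomycin
        spare        = A_fccp     - basal
        non_mito     = A_rotenone
        proton_leak  = A_oligomycin - A_rotenone

    Note the asymmetry: basal subtracts the post-medium window
    [80-95 min] while non-mitochondrial respiration and the other
    corrected parameters use the post-rotenone window [60-75 min].
    Both windows estimate non-mitochondrial O2 consumption and the
    asymmetry is reproduced deliberately; pass
    ``single_non_mito_window=True`` to use the rotenone window
    throughout (logged when active).
    """
    w = dict(DEFAULT_WINDOWS if windows is None else windows)
    avg = {k: _window_average(trace, w[k], k) for k in w}
    if single_non_mito_window:
        logger.info("using the post-rotenone window [%.0f-%.0f min] as the "
                    "single non-mitochondrial baseline", *w["rotenone"])
        avg["medium"] = avg["rotenone"]
    basal = avg["basal"] - avg["medium"]
    return MitoStressResult(
        basal=basal,
        maximal=avg["fccp"] - avg["rotenone"],
        atp_production=avg["basal"] - avg["oligomycin"],
        spare_capacity=avg["fccp"] - basal,
        non_mito=avg["rotenone"],
        proton_leak=avg["oligomycin"] - avg["rotenone"],
    )


def ddct_fold_change(
    plate: pd.DataFrame,
    mito_probe: str = "MT-ND1",
    nuclear_probe: str = NUCLEAR_PROBE,
    control_group: str = "control",
    sign_convention: str = "as_printed",
) -> pd.DataFrame:
    """Per-sample relative mtDNA content by the delta-delta-CT method.

    Parameters
    ----------
    plate
        Long-format CT table with columns ``sample``, ``probe``, ``ct``,
        ``group``.  Every sample needs a CT for both probes.
    sign_convention
        ``"as_printed"`` (default): fold = 2**ddCT, where
        dCT = CT_mito - CT_nuclear and ddCT = dCT_sample - mean(dCT_control).
        ``"canonical"``: fold = 2**(-ddCT), the usual convention under
        which a sample with more mtDNA (lower mito CT) shows fold > 1.

    The control aggregate is the arithmetic mean of control dCT values,
    i.e. the geometric mean on the fold scale; with multi-sample
    controls the control group's mean fold is therefore ~1 rather than
    exactly 1 (logged).

    Returns a DataFrame with columns sample, group, delta_ct,
    delta_delta_ct, fold_change.
    """
    if sign_convention not in ("as_printed", "canonical"):
        raise ValueError(f"unknown sign convention: {sign_convention!r}")
    wide = plate.pivot_table(index=["sample", "group"], columns="probe",
                             values="ct")
    for probe in (mito_probe, nuclear_probe):
        if probe not in wide.columns or wide[probe].isna().any():
            raise ValueError(f"missing CT values for probe {probe!r}")
    wide = wide.reset_index()
    dct = wide[mito_probe] - wide[nuclear_probe]
    control = wide["group"] == control_group
    if not control.any():
        raise ValueError(f"control group {control_group!r} is empty")
    if control.sum() > 1:
        logger.info("multi-sample control: mean fold of the control group "
                    "is a geometric, not arithmetic, unit")
    ddct = dct - dct[control].mean()
    sign = 1.0 if sign_convention == "as_printed" else -1.0
    return pd.DataFrame({
        "sample": wide["sample"],
        "group": wide["group"],
        "probe": mito_probe,
        "delta_ct": dct,
        "delta_delta_ct": ddct,
        "fold_change": 2.0 ** (sign * ddct),
    })


def mastermix_volumes(
    n_reactions: int,
    master_ul: float = 5.0,
    probe_ul: float = 0.5,
    water_ul: float = 3.5,
    overage_frac: float = 0.0,
) -> dict[str, float]:
    """Batch qPCR mastermix volumes (per-reaction total 9 uL by default).

    ``overage_frac`` adds pipetting overage, e.g. 0.1 for 10% extra.
    """
    if n_reactions < 0 or overage_frac < 0:
        raise ValueError("reaction count and overage must be non-negative")
    if min(master_ul, probe_ul, water_ul) < 0:
        raise ValueError("volumes must be non-negative")
    scale = n_reactions * (1.0 + overage_frac)
    per = master_ul + probe_ul + water_ul
    return {
        "per_reaction_ul": per,
        "master_ul": master_ul * scale,
        "probe_ul": probe_ul * scale,
        "water_ul": water_ul * scale,
        "total_ul": per * scale,
    }
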