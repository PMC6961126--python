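"""Synthetic data with known ground truth for every assay input class.

Four generators emulate the raw inputs of the analysis pipelines so
that parameter recovery can be tested end to end without any
instrument data: flow-cytometry event tables (calibration beads plus
lognormal cell-volume populations), multi-channel immunofluorescence
scenes (DAPI nuclei, sarcomeric texture, CellMask cytoplasm,
perinuclear BNP rings), mitostress OCR traces (five plateaus, three
measurements each), and qPCR CT plates (mito vs nuclear probes).

Every simulated object carries a truth record, and a fixed seed gives
bitwise-identical output.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .mito import OcrTrace
from .segmentation import ImageScene

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Flow cytometry
# ---------------------------------------------------------------------------

@dataclass
class FlowSim:
    """Simulated flow run: bead events, bead panel, cell events, truth."""

    bead_events: pd.DataFrame
    bead_panel: pd.DataFrame
    cell_events: pd.DataFrame
    truth: dict = field(default_factory=dict)


def _sphere_diameter(volume_um3: np.ndarray) -> np.ndarray:
    return (6.0 * volume_um3 / math.pi) ** (1.0 / 3.0)


def simulate_flow_events(
    bead_diameters_um=(5.0, 10.0, 15.0, 20.0, 25.0, 30.0),
    n_per_bead: int = 10_000,
    slope: float = 100.0,
    intercept: float = 50.0,
    noise_cv: float = 0.02,
    cell_pops: list[dict] | None = None,
    debris_frac: float = 0.0,
    seed: int = 0,
) -> FlowSim:
    """Simulate bead and cell scatter events through a known calibration.

    Bead FSC-A is ``(slope*d + intercept) * (1 + N(0, noise_cv))``;
    cell volumes are lognormal per population (``median_volume_um3``,
    ``geometric_sd``, ``n``) and inverted through the sphere formula to
    diameters before applying the same FSC model.  SSC-A scales with
    d^2 and SSC-W is narrow (singlets).  An optional low-FSC/low-SSC
    debris population can be mixed into the cell events.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    diam = np.asarray(bead_diameters_um, dtype=float)
    if np.any(diam <= 0):
        raise ValueError("bead diameters must be positive")
    rng = np.random.default_rng(seed)

    def _events(diameter, kind):
        n = diameter.size
        fsc = (slope * diameter + intercept) * \
            (1.0 + rng.normal(0.0, noise_cv, n))
        ssc = 0.5 * slope * diameter ** 2 * \
            (1.0 + rng.normal(0.0, max(noise_cv, 0.01), n))
        ssw = 1000.0 * (1.0 + rng.normal(0.0, 0.02, n))
        return pd.DataFrame({"fsc_area": np.abs(fsc),
                             "ssc_area": np.abs(ssc),
                             "ssc_width": np.abs(ssw),
                             "kind": kind})

    bead_frames = []
    for d in diam:
        ev = _events(np.full(n_per_bead, d), f"bead_{d:g}um")
        ev["diameter_um"] = d
        bead_frames.append(ev)
    bead_events = pd.concat(bead_frames, ignore_index=True)
    bead_panel = (bead_events.groupby("diameter_um")["fsc_area"]
                  .median().rename("fsc_median").reset_index())

    if cell_pops is None:
        cell_pops = [{"median_volume_um3": 4000.0, "geometric_sd": 1.5,
                      "n": 10_000}]
    cell_frames, truth_pops = [], []
    for i, pop in enumerate(cell_pops):
        med_v, gsd, n = (pop["median_volume_um3"], pop["geometric_sd"],
                         int(pop["n"]))
        volumes = np.exp(rng.normal(math.log(med_v), math.log(gsd), n))
        d = _sphere_diameter(volumes)
        ev = _events(d, f"pop_{i}")
        cell_frames.append(ev)
        truth_pops.append({"population": i, "median_volume_um3": med_v,
                           "geometric_sd": gsd, "n": n})
    cells = pd.concat(cell_frames, ignore_index=True)
    if debris_frac > 0:
        n_deb = int(debris_frac * len(cells) / (1 - debris_frac))
        deb = pd.DataFrame({
            "fsc_area": np.abs(rng.normal(0.2 * intercept, 20, n_deb))
            + intercept,
            "ssc_area": np.abs(rng.normal(30, 10, n_deb)),
            "ssc_width": np.abs(rng.normal(1000, 30, n_deb)),
            "kind": "debris"})
        cells = pd.concat([cells, deb], ignore_index=True)

    truth = {"seed": seed, "slope": slope, "intercept": intercept,
             "noise_cv": noise_cv, "populations": truth_pops,
             "debris_frac": debris_frac}
    return FlowSim(bead_events=bead_events, bead_panel=bead_panel,
                   cell_events=cells, truth=truth)


# ---------------------------------------------------------------------------
# Imaging scenes
# ---------------------------------------------------------------------------

#: Default mean intensity levels (arbitrary camera units).
DEFAULT_INTENSITY_LEVELS = {
    "dapi_nucleus": 600.0,
    "cellmask_cytoplasm": 300.0,
    "actinin_base": 120.0,        # 488 fill in cardiomyocytes
    "actinin_texture": 80.0,      # striation/texture amplitude
    "bnp_negative": 30.0,         # perinuclear ring mean per BNP class
    "bnp_medium": 240.0,
    "bnp_high": 900.0,
    "background": 10.0,
    "read_noise_sd": 2.0,
}

#: Physiological sarcomere spacing used for "organized" striations.
SARCOMERE_PERIOD_UM = 1.9

BNP_CLASSES = ("negative", "medium", "high")


def _ellipse_mask(shape, cy, cx, ry, rx, theta):
    yy, xx = np.indices(shape, dtype=float)
    dy, dx = yy - cy, xx - cx
    c, s = math.cos(theta), math.sin(theta)
    u = (c * dx + s * dy) / rx
    v = (-s * dx + c * dy) / ry
    return u ** 2 + v ** 2 <= 1.0


class _Window:
    """Local crop of the scene around one simulated cell."""

    def __init__(self, shape, cy, cx, half):
        self.y0 = max(int(cy - half), 0)
        self.x0 = max(int(cx - half), 0)
        self.y1 = min(int(cy + half) + 1, shape[0])
        self.x1 = min(int(cx + half) + 1, shape[1])
        self.shape = (self.y1 - self.y0, self.x1 - self.x0)

    @property
    def slices(self):
        return (slice(self.y0, self.y1), slice(self.x0, self.x1))

    def ellipse(self, cy, cx, ry, rx, theta):
        return _ellipse_mask(self.shape, cy - self.y0, cx - self.x0,
                             ry, rx, theta)


def simulate_image_scene(
    n_cells: int,
    pixel_size_um: float = 0.65,
    frac_non_cm: float = 0.0,
    nuclei_count_probs=(0.70, 0.25, 0.05),
    bnp_fracs=(1.0, 0.0, 0.0),
    frac_disarrayed: float = 0.0,
    intensity_levels: dict | None = None,
    grid_pitch_um: float = 50.0,
    sarcomere_period_um: float = SARCOMERE_PERIOD_UM,
    seed: int = 0,
    image_shape: tuple[int, int] | None = None,
) -> tuple[ImageScene, pd.DataFrame]:
    """Simulate one immunofluorescence field with per-cell ground truth.

    Cells are placed on a jittered grid (guaranteed non-overlapping at
    the default pitch).  Each cell gets: 1-3 elliptical nuclei (DAPI),
    a cytoplasm ellipse (CellMask, ch647), and — if it is a
    cardiomyocyte — 488 signal composed of a base fill, a zero-mean
    sarcomeric texture (coherent grating at the sarcomere period when
    organized; isotropic band-pass noise plus bright puncta when
    disarrayed) and a perinuclear BNP ring at its class level.
    Non-cardiomyocytes carry no 488 signal.  Camera noise is Poisson
    shot noise plus Gaussian read noise.

    Returns the scene and a per-cell truth table (one row per cell).
    """
    if not 0 <= frac_non_cm <= 1 or not 0 <= frac_disarrayed <= 1:
        raise ValueError("fractions must lie in [0, 1]")
    if abs(sum(bnp_fracs) - 1.0) > 1e-9:
        raise ValueError("bnp_fracs must sum to 1")
    lv = dict(DEFAULT_INTENSITY_LEVELS, **(intensity_levels or {}))
    rng = np.random.default_rng(seed)
    px = pixel_size_um
    pitch = grid_pitch_um / px
    margin = 25.0 / px

    n_cols = max(1, math.ceil(math.sqrt(max(n_cells, 1))))
    n_rows = max(1, math.ceil(max(n_cells, 1) / n_cols))
    shape = (int(n_rows * pitch + 2 * margin),
             int(n_cols * pitch + 2 * margin))
    if image_shape is not None:
        if image_shape[0] < shape[0] or image_shape[1] < shape[1]:
            raise ValueError(
                f"cannot place {n_cells} cells without overlap in "
                f"{image_shape}; need >= {shape} px (lower n_cells)")
        shape = image_shape

    dapi = np.zeros(shape)
    ch488 = np.zeros(shape)
    ch647 = np.zeros(shape)
    truth_rows = []
    half_win = pitch / 2.0 + 4.0 / px  # cells never leave their grid cell

    for i in range(n_cells):
        r, c = divmod(i, n_cols)
        cy = margin + (r + 0.5) * pitch + rng.uniform(-2, 2) / px
        cx = margin + (c + 0.5) * pitch + rng.uniform(-2, 2) / px
        is_cm = rng.random() >= frac_non_cm
        n_nuc = 1 + int(rng.choice(len(nuclei_count_probs),
                                   p=np.asarray(nuclei_count_probs)))
        bnp_class = BNP_CLASSES[int(rng.choice(3, p=np.asarray(bnp_fracs)))]
        disarrayed = bool(rng.random() < frac_disarrayed) if is_cm else False

        win = _Window(shape, cy, cx, half_win)
        rc = rng.uniform(13.0, 16.0) / px           # cytoplasm radius, px
        cyto = win.ellipse(cy, cx, rc * rng.uniform(0.85, 1.0),
                           rc, rng.uniform(0, math.pi))
        level = lv["cellmask_cytoplasm"] * rng.uniform(0.8, 1.2)
        view647 = ch647[win.slices]
        view647[cyto] = np.maximum(view647[cyto], level)

        # nuclei: first centred, siblings offset with a 1-2.5 um
        # edge-to-edge gap so cluster-by-distance (5 um) groups them
        # into one cell while nuclei of neighbouring cells stay far
        rn_um = rng.uniform(6.2, 6.8)
        rn = rn_um / px
        rn_sib_um = rng.uniform(6.0, 6.4)
        centers = [(cy, cx, rn)]
        for k in range(1, n_nuc):
            gap = rng.uniform(1.2, 2.8)
            ang = rng.uniform(0, 2 * math.pi)
            off = (rn_um + rn_sib_um + gap) / px
            sign = 1 if k == 1 else -1
            centers.append((cy + off * math.sin(ang) * sign,
                            cx + off * math.cos(ang) * sign,
                            rn_sib_um / px))
        nuc_mask = np.zeros(win.shape, dtype=bool)
        for (ny, nx, rr) in centers:
            ecc = rng.uniform(0.92, 1.0)
            nuc_mask |= win.ellipse(ny, nx, rr * ecc, rr,
                                    rng.uniform(0, math.pi))
        dapi[win.slices][nuc_mask] = lv["dapi_nucleus"] * \
            rng.uniform(0.9, 1.1)

        if is_cm:
            base = lv["actinin_base"] * rng.uniform(0.8, 1.2)
            amp = lv["actinin_texture"] * rng.uniform(0.8, 1.2)
            tex = _sarcomere_texture(win.shape, cyto, disarrayed,
                                     sarcomere_period_um / px, rng)
            view488 = ch488[win.slices]
            view488[cyto] += base + amp * tex[cyto]
            # perinuclear BNP ring: nucleus edge outward by 75% of r_eq
            ring = _ring_mask(nuc_mask, 0.75)
            ring_level = lv[f"bnp_{bnp_class}"] * \
                math.exp(rng.normal(0.0, 0.25))
            view488[ring] += ring_level
        else:
            ring_level = 0.0

        truth_rows.append({
            "cell_id": i, "center_y_um": cy * px, "center_x_um": cx * px,
            "is_cardiomyocyte": is_cm, "nuclei_count": n_nuc,
            "bnp_class": bnp_class if is_cm else "none",
            "bnp_ring_level": ring_level,
            "disarrayed": disarrayed,
        })

    scene_channels = {}
    for name, chan in (("dapi", dapi), ("ch488", ch488), ("ch647", ch647)):
        blurred = ndi.gaussian_filter(chan + lv["background"], 1.0)
        noisy = rng.poisson(np.maximum(blurred, 0)).astype(float)
        noisy += rng.normal(0.0, lv["read_noise_sd"], shape)
        n_neg = int(np.sum(noisy < 0))
        if n_neg:
            logger.debug("%s: floored %d negative pixels at 0", name, n_neg)
        scene_channels[name] = np.maximum(noisy, 0.0)

    scene = ImageScene(channels=scene_channels, pixel_size_um=px)
    return scene, pd.DataFrame(truth_rows)


def _ring_mask(nuc_mask: np.ndarray, expand_fraction: float) -> np.ndarray:
    r_eq = math.sqrt(nuc_mask.sum() / math.pi)
    dist = ndi.distance_transform_edt(~nuc_mask)
    return (dist <= expand_fraction * r_eq) & ~nuc_mask


def _sarcomere_texture(shape, cyto, disarrayed, period_px, rng):
    """Zero-mean texture field: coherent grating or decorrelated noise.

    Organized cells get a single-orientation sinusoidal grating at the
    sarcomere period.  Disarray is modelled as orientation
    decorrelation: isotropic band-pass noise at the same spatial band
    plus bright puncta (aggregated sarcomeric protein).
    """
    sl = ndi.find_objects(cyto.astype(np.int8))[0]
    sub_shape = (sl[0].stop - sl[0].start, sl[1].stop - sl[1].start)
    tex = np.zeros(shape)
    if not disarrayed:
        theta = rng.uniform(0, math.pi)
        yy, xx = np.indices(sub_shape, dtype=float)
        phase = rng.uniform(0, 2 * math.pi)
        grating = np.sin(2 * math.pi *
                         (xx * math.cos(theta) + yy * math.sin(theta))
                         / period_px + phase)
        tex[sl] = grating
    else:
        noise = rng.normal(size=sub_shape)
        band = ndi.gaussian_filter(noise, period_px / 3.0) \
            - ndi.gaussian_filter(noise, period_px)
        sd = band.std()
        band = band / sd if sd > 0 else band
        # puncta: a few bright aggregates
        n_pts = max(3, int(0.02 * sub_shape[0] * sub_shape[1] / 25))
        pts = np.zeros(sub_shape)
        ys = rng.integers(0, sub_shape[0], n_pts)
        xs = rng.integers(0, sub_shape[1], n_pts)
        pts[ys, xs] = rng.uniform(5, 10, n_pts)
        band = band + ndi.gaussian_filter(pts, 1.0)
        tex[sl] = band
    return tex


# ---------------------------------------------------------------------------
# OCR traces
# ---------------------------------------------------------------------------

DEFAULT_PLATEAUS = {"basal": 200.0, "post_oligo": 100.0, "post_fccp": 300.0,
                    "post_rote": 50.0, "post_medium": 50.0}

_WINDOW_ORDER = ("basal", "post_oligo", "post_fccp", "post_rote",
                 "post_medium")
_WINDOW_STARTS = (0.0, 20.0, 40.0, 60.0, 80.0)


def simulate_ocr_trace(
    plateaus: dict | None = None,
    cell_count: int = 50_000,
    noise_cv: float = 0.0,
    seed: int = 0,
    well: str = "A1",
) -> tuple[OcrTrace, dict]:
    """Simulate one well's mitostress OCR trace.

    Three measurements per phase at 2.5, 7.5 and 12.5 min into each
    15-min window (windows starting at 0, 20, 40, 60, 80 min), with
    multiplicative Gaussian noise of the given CV.  Negative draws are
    floored at 0 with a logged count.
    """
    plat = dict(DEFAULT_PLATEAUS, **(plateaus or {}))
    rng = np.random.default_rng(seed)
    times, values = [], []
    for name, start in zip(_WINDOW_ORDER, _WINDOW_STARTS):
        for off in (2.5, 7.5, 12.5):
            times.append(start + off)
            values.append(plat[name] * (1.0 + rng.normal(0.0, noise_cv)))
    values = np.asarray(values)
    n_neg = int(np.sum(values < 0))
    if n_neg:
        logger.info("floored %d negative OCR draws at 0", n_neg)
    values = np.maximum(values, 0.0)
    trace = OcrTrace(time_min=np.asarray(times), ocr=values,
                     cell_count=cell_count, well=well,
                     injections={"oligomycin": 16.0, "FCCP": 36.0,
                                 "rotenone": 56.0, "medium": 76.0})
    truth = {"seed": seed, "plateaus": plat, "cell_count": cell_count,
             "noise_cv": noise_cv}
    return trace, truth


# ---------------------------------------------------------------------------
# qPCR plates
# ---------------------------------------------------------------------------

def simulate_qpcr_plate(
    n_control: int = 10,
    n_case: int = 10,
    ct_nuclear_mean: float = 24.0,
    delta_ct_control: float = -6.0,
    true_fold_case: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    mito_probes=("MT-ND1", "MT-ND2"),
) -> tuple[pd.DataFrame, dict]:
    """Simulate a CT table for mito/nuclear content quantification.

    Control samples have dCT (mito - nuclear) = ``delta_ct_control``;
    case samples carry ``true_fold_case`` times the control mtDNA
    content, i.e. their mito CT is shifted by -log2(fold).  Gaussian
    CT noise of ``noise_sd`` cycles is added per well.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for group, n, fold in (("control", n_control, 1.0),
                           ("case", n_case, true_fold_case)):
        for i in range(n):
            sample = f"{group}_{i}"
            ct_nuc = ct_nuclear_mean + rng.normal(0.0, 0.3)
            rows.append({"sample": sample, "group": group, "probe": "ACTB",
                         "ct": ct_nuc + rng.normal(0.0, noise_sd)})
            for probe in mito_probes:
                ct_mito = ct_nuc + delta_ct_control - math.log2(fold)
                rows.append({"sample": sample, "group": group,
                             "probe": probe,
                             "ct": ct_mito + rng.normal(0.0, noise_sd)})
    truth = {"seed": seed, "true_fold_case": true_fold_case,
             "delta_ct_control": delta_ct_control, "noise_sd": noise_sd}
    return pd.DataFrame(rows), truth
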