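"""Ground-truth-annotated synthetic metaphase plates, calibration targets and
flow-cytometry histograms.

The renderer emulates Feulgen-stained mitotic chromosomes imaged in
transmitted light with a 12-bit camera.  Each chromosome is a curved capsule
(a tube of varying width around a smooth medial axis) whose width narrows in
a Gaussian dip at the primary constriction (centromere) and, for the
satellited pair, at the secondary (NOR) constriction.  Stoichiometric
staining is modelled by Beer-Lambert absorbance: the areal optical density
of each arm integrates exactly to that arm's declared DNA amount times a
single slide-wide constant (``ImageParams.iod_per_pg``), so the proportional
allocation downstream is exactly recoverable.  Heterochromatic knobs are
blocks of elevated density on the long arms: DNA within an arm is
distributed with knob-weighted density, concentrating mass in the knob while
keeping the arm total fixed.

Pixel intensity is I(p) = clip(round(I0 * g(p) * 10**(-OD(p)) + noise)),
with g a linear illumination gradient and noise Gaussian and/or Poisson.
The default karyotype is maize-like: 2n = 2x = 20, two metacentric pairs
(1 and 5), eight submetacentric (2-4, 6-10), a satellite on the short arm
of pair 6, and knobs on the long arms of pairs 2-9.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.ndimage import binary_dilation
from scipy.spatial import cKDTree
from skimage.measure import find_contours
from skimage.morphology import disk

from . import reference
from .errors import PlacementError, ValidationError
from .fcm import FCMHistogram

#: Relative depth of the Gaussian width dip at a constriction.
CONSTRICTION_DEPTH = 0.4
#: Width-dip standard deviation at the centromere (um).
CENTROMERE_DIP_SD_UM = 0.8
#: Width-dip standard deviation at the secondary (NOR) constriction (um);
#: narrower than the centromere dip so it fits inside the satellite.
SECONDARY_DIP_SD_UM = 0.3

#: um^2 of chromosome area per pg of pair 2C DNA (per homolog); anchored on
#: the published area of chromosome 1 (9.478 um^2) and its pair DNA 0.803 pg.
AREA_UM2_PER_PAIR_PG = 9.478 / 0.803
#: Integrated OD per pg (per homolog IOD = dna_pair/2 * this); anchored on the
#: published chromosome-1 IOD (10.679) at 0.803/2 pg.
DEFAULT_IOD_PER_PG = 10.679 / (0.803 / 2.0)

_REGION_CODES = {"SAT": 0, "S": 1, "L": 2}
_REGION_NAMES = {v: k for k, v in _REGION_CODES.items()}


# ---------------------------------------------------------------------------
# Karyotype specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KnobBlock:
    """A heterochromatic knob: elevated-density block on one arm."""

    arm: str  # "S" or "L"
    rel_pos: float  # centre position along the arm, 0 (proximal) .. 1 (distal)
    length_um: float
    density_mult: float  # >= 1

    def __post_init__(self):
        if self.arm not in ("S", "L"):
            raise ValidationError("knob arm must be 'S' or 'L'")
        if not 0.0 <= self.rel_pos <= 1.0:
            raise ValidationError("knob rel_pos must be in [0, 1]")
        if self.length_um <= 0 or self.density_mult < 1.0:
            raise ValidationError("knob length must be > 0 and multiplier >= 1")


@dataclass(frozen=True)
class ChromosomePairSpec:
    """Geometry and DNA content of one homologous pair.

    Lengths are tip-to-tip (they include the rounded telomeric caps).  The
    satellite length is distal to the secondary constriction on the short
    arm; 0 means no satellite.  ``arm_dna_fractions`` splits the pair's 2C
    DNA over the portions S / L / SAT and must sum to 1.
    """

    pair_id: int
    short_arm_um: float
    long_arm_um: float
    dna_pair_2C_pg: float
    satellite_um: float = 0.0
    arm_dna_fractions: dict = field(default_factory=dict)
    knobs: tuple[KnobBlock, ...] = ()
    width_um: float = 1.1
    copies: int = 2

    def __post_init__(self):
        if self.short_arm_um <= 0 or self.long_arm_um <= 0 or self.width_um <= 0:
            raise ValidationError("arm lengths and width must be positive")
        if self.satellite_um < 0:
            raise ValidationError("satellite length must be >= 0")
        if self.dna_pair_2C_pg <= 0:
            raise ValidationError("pair DNA must be positive")
        fr = dict(self.arm_dna_fractions) or (
            {"S": self.short_arm_um / (self.short_arm_um + self.long_arm_um),
             "L": self.long_arm_um / (self.short_arm_um + self.long_arm_um)}
        )
        if self.satellite_um > 0 and "SAT" not in fr:
            raise ValidationError("satellited pair needs a SAT DNA fraction")
        if abs(sum(fr.values()) - 1.0) > 1e-9:
            raise ValidationError("arm DNA fractions must sum to 1")
        object.__setattr__(self, "arm_dna_fractions", fr)

    @property
    def total_um(self) -> float:
        return self.short_arm_um + self.long_arm_um + self.satellite_um

    @property
    def arm_ratio(self) -> float:
        return self.long_arm_um / self.short_arm_um

    def arm_dna_pg(self, arm: str) -> float:
        """2C DNA of one portion of the pair (pg)."""
        return self.dna_pair_2C_pg * self.arm_dna_fractions.get(arm, 0.0)


@dataclass(frozen=True)
class KaryotypeSpec:
    """A full karyotype: the pair specs plus the nuclear 2C they sum to."""

    pairs: tuple[ChromosomePairSpec, ...]
    nuclear_2C_pg: float

    def __post_init__(self):
        ids = [p.pair_id for p in self.pairs]
        if len(set(ids)) != len(ids):
            raise ValidationError("pair ids must be unique")
        total = sum(p.dna_pair_2C_pg for p in self.pairs)
        if abs(total - self.nuclear_2C_pg) > 1e-9:
            raise ValidationError(
                f"pair DNA sums to {total:.6f} pg != nuclear 2C {self.nuclear_2C_pg:.6f}"
            )

    def pair(self, pair_id: int) -> ChromosomePairSpec:
        for p in self.pairs:
            if p.pair_id == pair_id:
                return p
        raise KeyError(pair_id)

    def to_json(self, path) -> None:
        payload = {
            "nuclear_2C_pg": self.nuclear_2C_pg,
            "pairs": [
                {**asdict(p), "knobs": [asdict(k) for k in p.knobs]}
                for p in self.pairs
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "KaryotypeSpec":
        with open(path) as fh:
            payload = json.load(fh)
        pairs = tuple(
            ChromosomePairSpec(
                **{**p, "knobs": tuple(KnobBlock(**k) for k in p["knobs"])}
            )
            for p in payload["pairs"]
        )
        return cls(pairs, payload["nuclear_2C_pg"])


#: Default arm ratios (long/short) per pair: <1.5 metacentric-class (m) for
#: pairs 1 and 5, 1.5-3.0 submetacentric (sm) for the rest.
_DEFAULT_ARM_RATIOS = {
    1: 1.15, 2: 1.75, 3: 2.05, 4: 1.65, 5: 1.30,
    6: 1.70, 7: 2.40, 8: 2.65, 9: 1.85, 10: 2.10,
}
#: Default knob density multipliers on long arms (pairs 2-9).
_DEFAULT_KNOB_MULT = {2: 1.9, 3: 1.8, 4: 1.7, 5: None, 6: 1.6, 7: 1.9, 8: 2.0, 9: 2.0}
#: Satellite length sized to its DNA share (like chromosome areas, the
#: satellite's area tracks its DNA so its stain density matches the body).
_DEFAULT_SAT_UM = 1.0
_DEFAULT_WIDTH_UM = 1.1


def default_maize_spec(seed: int = 0) -> KaryotypeSpec:
    """Build the default maize-like karyotype specification.

    DNA amounts per pair, arm and satellite are the published per-arm 2C
    values; chromosome areas scale with pair DNA to match the printed area
    anchors at the default width; arm ratios put pairs 1 and 5 in the
    metacentric class and the others in the submetacentric class; the
    satellite sits on pair 6 and knobs on the long arms of pairs 2-9.

    The default table is deterministic; ``seed`` is accepted for interface
    symmetry with the renderers and reserved for future jittered variants.
    """
    del seed
    pairs = []
    for pid, arms in reference.TABLE_2C_ARM_PG.items():
        dna = sum(v[0] for v in arms.values())
        fractions = {arm: v[0] / dna for arm, v in arms.items()}
        W0 = _DEFAULT_WIDTH_UM
        sat_um = _DEFAULT_SAT_UM if "SAT" in arms else 0.0
        n_dips = 1 + (1 if sat_um else 0)
        dip_area = CONSTRICTION_DEPTH * W0 * math.sqrt(2 * math.pi) * CENTROMERE_DIP_SD_UM
        sec_area = CONSTRICTION_DEPTH * W0 * math.sqrt(2 * math.pi) * SECONDARY_DIP_SD_UM
        target_area = dna * AREA_UM2_PER_PAIR_PG
        lost = dip_area + (sec_area if sat_um else 0.0)
        axis_len = (target_area - math.pi * W0 * W0 / 4.0 + lost) / W0
        total = axis_len + W0  # tip-to-tip
        r = _DEFAULT_ARM_RATIOS[pid]
        # the ratio applies to long / (short + satellite): the class is then
        # the same whether or not the satellite is counted with the short arm
        short_side = total / (1.0 + r)
        short_um = short_side - sat_um
        long_um = total - short_side
        knobs = ()
        mult = _DEFAULT_KNOB_MULT.get(pid)
        if mult:
            knobs = (KnobBlock("L", 0.5, 1.0, mult),)
        pairs.append(
            ChromosomePairSpec(
                pair_id=pid,
                short_arm_um=short_um,
                long_arm_um=long_um,
                satellite_um=sat_um,
                dna_pair_2C_pg=dna,
                arm_dna_fractions=fractions,
                knobs=knobs,
                width_um=W0,
            )
        )
    nuclear = sum(p.dna_pair_2C_pg for p in pairs)
    return KaryotypeSpec(tuple(pairs), nuclear)


# ---------------------------------------------------------------------------
# Imaging parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ImageParams:
    """Acquisition model for the simulated camera and slide."""

    bit_depth: int = 12
    background: float = 3000.0  # I0, counts
    pixel_size_um: float = 0.08
    noise_sd: float = 8.0  # Gaussian read noise, counts
    poisson: bool = False
    gradient_amplitude: float = 0.0  # relative left-right illumination slope
    canvas_shape: tuple[int, int] = (560, 560)
    iod_per_pg: float = DEFAULT_IOD_PER_PG
    margin_px: int = 3  # minimum clearance between chromosomes
    seed: int = 0

    def __post_init__(self):
        if self.bit_depth not in (8, 12, 16):
            raise ValidationError("bit depth must be 8, 12 or 16")
        if not 0 < self.background < 2 ** self.bit_depth:
            raise ValidationError("background must satisfy 0 < I0 < 2**bit_depth")
        if self.pixel_size_um <= 0:
            raise ValidationError("pixel size must be positive")

    @property
    def max_count(self) -> int:
        return 2 ** self.bit_depth - 1

    @property
    def pixel_area_um2(self) -> float:
        return self.pixel_size_um ** 2


@dataclass
class MetaphaseImage:
    """A rendered metaphase plate (quantized counts)."""

    pixels: np.ndarray  # uint16
    pixel_size_um: float
    bit_depth: int
    background: float

    def to_tiff(self, path) -> None:
        import tifffile

        tifffile.imwrite(path, self.pixels, photometric="minisblack")


@dataclass
class ChromosomeTruth:
    """Ground truth for one rendered chromosome."""

    pair_id: int
    homolog: int  # 0 or 1
    bbox: tuple[int, int, int, int]  # r0, r1, c0, c1 (half-open)
    mask_local: np.ndarray  # bool, bbox frame
    region_local: np.ndarray  # uint8, 0 SAT / 1 S / 2 L / 255 outside
    axis_px: np.ndarray  # (n, 2) float, (row, col) canvas coordinates
    length_um: float  # tip-to-tip
    centromere_s_um: float  # arc position from the satellite-side tip
    centromere_px: tuple[float, float]
    satellite_s_um: float | None
    arm_dna_pg: dict  # portion -> 2C pg per homolog... keyed S/L/SAT, per homolog
    arm_iod: dict  # portion -> true integrated OD
    iod: float

    def full_mask(self, shape) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        r0, r1, c0, c1 = self.bbox
        m[r0:r1, c0:c1] = self.mask_local
        return m

    def polygon(self) -> np.ndarray:
        """Largest outline contour in canvas (row, col) coordinates."""
        padded = np.pad(self.mask_local.astype(float), 1)
        contours = find_contours(padded, 0.5)
        contour = max(contours, key=len)
        r0, _, c0, _ = self.bbox
        return contour - 1.0 + np.array([r0, c0], dtype=float)


@dataclass
class GroundTruth:
    """Per-image ground truth: chromosomes, the noiseless OD field, scales."""

    chromosomes: list
    od_true: np.ndarray
    iod_per_pg: float
    params: ImageParams
    spec: KaryotypeSpec

    def to_json(self, path) -> None:
        payload = {
            "iod_per_pg": self.iod_per_pg,
            "pixel_size_um": self.params.pixel_size_um,
            "chromosomes": [
                {
                    "pair_id": t.pair_id,
                    "homolog": t.homolog,
                    "length_um": t.length_um,
                    "centromere_s_um": t.centromere_s_um,
                    "satellite_s_um": t.satellite_s_um,
                    "arm_dna_pg": t.arm_dna_pg,
                    "arm_iod": t.arm_iod,
                    "iod": t.iod,
                    "polygon_rc": t.polygon().tolist(),
                }
                for t in self.chromosomes
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


# ---------------------------------------------------------------------------
# Chromosome geometry
# ---------------------------------------------------------------------------

def _chromosome_geometry(pair: ChromosomePairSpec, rng: np.random.Generator,
                         pixel_size_um: float, straight: bool = False):
    """Sample a curved medial axis with width, weight and region profiles.

    Returns (xy_um centred at 0, s_tip, width_um, weights, region codes).
    s_tip is the arc position measured from the satellite-side tip including
    the telomeric cap radius, so it runs from W0/2 to total - W0/2 along the
    axis samples.
    """
    W0 = pair.width_um
    total = pair.total_um
    axis_len = total - W0
    if axis_len <= 0:
        raise ValidationError("chromosome shorter than its width")
    ds = pixel_size_um * 0.5
    n = max(int(round(axis_len / ds)) + 1, 8)
    s = np.linspace(0.0, axis_len, n)
    theta0 = rng.uniform(0.0, 2.0 * math.pi)
    bend = rng.uniform(0.25, 0.5) * (1.0 if rng.random() < 0.5 else -1.0)
    phase = rng.uniform(0.0, 2.0 * math.pi)
    if straight:
        theta = np.full(n, theta0)
    else:
        theta = theta0 + bend * np.sin(math.pi * s / axis_len + phase)
    dx, dy = np.cos(theta), np.sin(theta)
    step = np.diff(s)
    x = np.concatenate([[0.0], np.cumsum(0.5 * (dx[1:] + dx[:-1]) * step)])
    y = np.concatenate([[0.0], np.cumsum(0.5 * (dy[1:] + dy[:-1]) * step)])
    xy = np.stack([x - x.mean(), y - y.mean()], axis=1)

    s_tip = s + W0 / 2.0
    cen_tip = pair.satellite_um + pair.short_arm_um
    width = W0 * (
        1.0
        - CONSTRICTION_DEPTH
        * np.exp(-0.5 * ((s_tip - cen_tip) / CENTROMERE_DIP_SD_UM) ** 2)
    )
    if pair.satellite_um > 0:
        width *= (
            1.0
            - CONSTRICTION_DEPTH
            * np.exp(-0.5 * ((s_tip - pair.satellite_um) / SECONDARY_DIP_SD_UM) ** 2)
        )

    weights = np.ones(n)
    for knob in pair.knobs:
        if knob.arm == "L":
            centre = cen_tip + knob.rel_pos * pair.long_arm_um
        else:
            centre = pair.satellite_um + (1.0 - knob.rel_pos) * pair.short_arm_um
        a, b = centre - knob.length_um / 2.0, centre + knob.length_um / 2.0
        weights[(s_tip >= a) & (s_tip < b)] = knob.density_mult

    region = np.full(n, _REGION_CODES["L"], dtype=np.uint8)
    region[s_tip < cen_tip] = _REGION_CODES["S"]
    if pair.satellite_um > 0:
        region[s_tip < pair.satellite_um] = _REGION_CODES["SAT"]
    return xy, s_tip, width, weights, region


def _rasterize(axis_px, width_um, pixel_size_um, canvas_shape, bbox_pad):
    """Pixels inside the union of disks of radius width/2 along the axis.

    Returns (bbox, mask_local, nearest_axis_index_local) or None when the
    capsule leaves the canvas.
    """
    H, W = canvas_shape
    rad_px = width_um.max() / 2.0 / pixel_size_um
    r0 = int(np.floor(axis_px[:, 0].min() - rad_px)) - bbox_pad
    r1 = int(np.ceil(axis_px[:, 0].max() + rad_px)) + bbox_pad + 1
    c0 = int(np.floor(axis_px[:, 1].min() - rad_px)) - bbox_pad
    c1 = int(np.ceil(axis_px[:, 1].max() + rad_px)) + bbox_pad + 1
    if r0 < 0 or c0 < 0 or r1 > H or c1 > W:
        return None
    rr, cc = np.mgrid[r0:r1, c0:c1]
    pts = np.stack([rr.ravel(), cc.ravel()], axis=1).astype(float)
    tree = cKDTree(axis_px)
    k = min(4, len(axis_px))
    dist, idx = tree.query(pts, k=k)
    if k == 1:
        dist, idx = dist[:, None], idx[:, None]
    inside = (dist * pixel_size_um <= width_um[idx] / 2.0).any(axis=1)
    mask = inside.reshape(rr.shape)
    nearest = idx[:, 0].reshape(rr.shape)
    return (r0, r1, c0, c1), mask, nearest


def render_metaphase(
    spec: KaryotypeSpec,
    params: ImageParams,
    straight: bool = False,
    max_attempts: int = 400,
) -> tuple[MetaphaseImage, GroundTruth]:
    """Render one metaphase plate with per-chromosome ground truth.

    Chromosome placement is rejection-sampled: positions and orientations
    are drawn until each capsule fits the canvas without touching any
    previously placed chromosome (clearance ``params.margin_px``).  Raises
    ``PlacementError`` when a chromosome cannot be placed within
    ``max_attempts`` draws, naming the offender.

    Identical ``spec``/``params`` (including the seed) give bit-identical
    images.
    """
    rng = np.random.default_rng(params.seed)
    H, W = params.canvas_shape
    px = params.pixel_size_um
    a_px = params.pixel_area_um2
    K = params.iod_per_pg
    od = np.zeros((H, W), dtype=np.float64)
    occupied_dil = np.zeros((H, W), dtype=bool)
    selem = disk(params.margin_px)
    truths: list[ChromosomeTruth] = []

    order = sorted(spec.pairs, key=lambda p: -p.total_um)
    for pair in order:
        for homolog in range(pair.copies):
            placed = None
            for _ in range(max_attempts):
                xy, s_tip, width, weights, region = _chromosome_geometry(
                    pair, rng, px, straight=straight
                )
                rad = pair.width_um / 2.0
                margin_um = rad + (params.margin_px + 3) * px
                lo_r = -xy[:, 1].min() + margin_um
                hi_r = H * px - xy[:, 1].max() - margin_um
                lo_c = -xy[:, 0].min() + margin_um
                hi_c = W * px - xy[:, 0].max() - margin_um
                if hi_r <= lo_r or hi_c <= lo_c:
                    continue
                centre = (rng.uniform(lo_r, hi_r), rng.uniform(lo_c, hi_c))
                axis_px = np.stack(
                    [(xy[:, 1] + centre[0]) / px, (xy[:, 0] + centre[1]) / px], axis=1
                )
                # coarse clearance test on the axis before full rasterization
                ar = np.clip(np.rint(axis_px[:, 0]).astype(int), 0, H - 1)
                ac = np.clip(np.rint(axis_px[:, 1]).astype(int), 0, W - 1)
                if occupied_dil[ar, ac].any():
                    continue
                ras = _rasterize(axis_px, width, px, (H, W), bbox_pad=2)
                if ras is None:
                    continue
                bbox, mask_local, nearest = ras
                r0, r1, c0, c1 = bbox
                if (mask_local & occupied_dil[r0:r1, c0:c1]).any():
                    continue
                placed = (bbox, mask_local, nearest, axis_px, s_tip, width, weights, region)
                break
            if placed is None:
                raise PlacementError(
                    f"could not place pair {pair.pair_id} homolog {homolog} on a "
                    f"{H}x{W} px canvas ({H * px:.0f}x{W * px:.0f} um) after "
                    f"{max_attempts} attempts; enlarge the canvas or shrink margins"
                )
            bbox, mask_local, nearest, axis_px, s_tip, width, weights, region = placed
            r0, r1, c0, c1 = bbox
            near_idx = nearest[mask_local]
            pix_region = region[near_idx]
            pix_weight = weights[near_idx]
            od_local = np.zeros(mask_local.shape, dtype=np.float64)
            arm_iod: dict[str, float] = {}
            arm_dna: dict[str, float] = {}
            region_local = np.full(mask_local.shape, 255, dtype=np.uint8)
            rows, cols = np.nonzero(mask_local)
            region_local[rows, cols] = pix_region
            for code, arm in _REGION_NAMES.items():
                frac = pair.arm_dna_fractions.get(arm, 0.0)
                sel = pix_region == code
                if frac <= 0.0 or not sel.any():
                    continue
                dna_h = pair.dna_pair_2C_pg * frac / 2.0  # per homolog
                wsum = pix_weight[sel].sum() * a_px
                od_local[rows[sel], cols[sel]] = dna_h * K * pix_weight[sel] / wsum
                arm_iod[arm] = dna_h * K
                arm_dna[arm] = dna_h
            od[r0:r1, c0:c1] += od_local
            occupied_dil[r0:r1, c0:c1] |= binary_dilation(mask_local, structure=selem)
            cen_s = pair.satellite_um + pair.short_arm_um
            cen_idx = int(np.argmin(np.abs(s_tip - cen_s)))
            truths.append(
                ChromosomeTruth(
                    pair_id=pair.pair_id,
                    homolog=homolog,
                    bbox=bbox,
                    mask_local=mask_local,
                    region_local=region_local,
                    axis_px=axis_px,
                    length_um=pair.total_um,
                    centromere_s_um=cen_s,
                    centromere_px=tuple(axis_px[cen_idx]),
                    satellite_s_um=pair.satellite_um if pair.satellite_um > 0 else None,
                    arm_dna_pg=arm_dna,
                    arm_iod=arm_iod,
                    iod=sum(arm_iod.values()),
                )
            )

    cols = np.arange(W, dtype=np.float64)
    g = 1.0 + params.gradient_amplitude * (cols / max(W - 1, 1) - 0.5)
    intensity = params.background * g[None, :] * np.power(10.0, -od)
    if params.poisson:
        intensity = rng.poisson(intensity).astype(np.float64)
    if params.noise_sd > 0:
        intensity = intensity + rng.normal(0.0, params.noise_sd, size=intensity.shape)
    pixels = np.clip(np.rint(intensity), 0, params.max_count).astype(np.uint16)
    image = MetaphaseImage(pixels, px, params.bit_depth, params.background)
    truth = GroundTruth(truths, od, K, params, spec)
    return image, truth


def render_touching_fixture(params: ImageParams, spec: KaryotypeSpec | None = None):
    """A plate where two chromosomes touch tip-to-tip amid isolated ones.

    The two homologs of the largest pair are laid out horizontally with
    their telomeric caps slightly interpenetrating (one merged binary
    object), plus the two homologs of the smallest pair placed separately
    as a size reference.  A deliberate stress fixture for the watershed
    splitter; returns the same (image, truth) bundle as
    ``render_metaphase``.
    """
    spec = spec or default_maize_spec()
    pair_big = spec.pairs[0]
    pair_small = spec.pairs[-1]
    rng = np.random.default_rng(params.seed)
    H, W = params.canvas_shape
    px = params.pixel_size_um
    od = np.zeros((H, W))
    truths = []

    def _paint(pair, homolog, row_px, col_start_px):
        xy, s_tip, width, weights, region = _chromosome_geometry(
            pair, rng, px, straight=True
        )
        n = len(xy)
        axis_c = col_start_px + (pair.width_um / 2.0) / px + np.linspace(
            0, (pair.total_um - pair.width_um) / px, n
        )
        axis_px = np.stack([np.full(n, row_px), axis_c], axis=1)
        ras = _rasterize(axis_px, width, px, (H, W), bbox_pad=2)
        if ras is None:
            raise PlacementError("touching fixture does not fit the canvas")
        bbox, mask_local, nearest = ras
        r0, r1, c0, c1 = bbox
        near_idx = nearest[mask_local]
        pix_weight = weights[near_idx]
        rows, cols_ = np.nonzero(mask_local)
        dna_h = pair.dna_pair_2C_pg / 2.0
        wsum = pix_weight.sum() * params.pixel_area_um2
        od_loc = np.zeros(mask_local.shape)
        od_loc[rows, cols_] = dna_h * params.iod_per_pg * pix_weight / wsum
        od[r0:r1, c0:c1] += od_loc
        region_local = np.full(mask_local.shape, 255, dtype=np.uint8)
        region_local[rows, cols_] = region[near_idx]
        truths.append(
            ChromosomeTruth(
                pair_id=pair.pair_id, homolog=homolog, bbox=bbox,
                mask_local=mask_local, region_local=region_local, axis_px=axis_px,
                length_um=pair.total_um,
                centromere_s_um=pair.satellite_um + pair.short_arm_um,
                centromere_px=(row_px, float(axis_c[0])),
                satellite_s_um=pair.satellite_um or None,
                arm_dna_pg={}, arm_iod={}, iod=dna_h * params.iod_per_pg,
            )
        )

    total_px = pair_big.total_um / px
    # shallow tip interpenetration: merged object with a narrow waist the
    # distance-transform markers can separate
    overlap_px = 0.1 * pair_big.width_um / px
    start_c = W / 2.0 - total_px
    _paint(pair_big, 0, H / 2.0, start_c)
    _paint(pair_big, 1, H / 2.0, start_c + total_px - overlap_px)
    small_px = pair_small.total_um / px
    _paint(pair_small, 0, H / 4.0, W / 2.0 - 1.5 * small_px)
    _paint(pair_small, 1, H / 4.0, W / 2.0 + 0.5 * small_px)

    intensity = params.background * np.power(10.0, -od)
    if params.noise_sd > 0:
        intensity = intensity + rng.normal(0.0, params.noise_sd, size=intensity.shape)
    pixels = np.clip(np.rint(intensity), 0, params.max_count).astype(np.uint16)
    return MetaphaseImage(pixels, px, params.bit_depth, params.background), GroundTruth(
        truths, od, params.iod_per_pg, params, spec
    )


# ---------------------------------------------------------------------------
# Calibration targets
# ---------------------------------------------------------------------------

@dataclass
class CalibrationTargets:
    """Synthetic stepped-density filter and blank-field images (float counts)."""

    stepped_image: np.ndarray
    blank_image: np.ndarray
    step_ods: np.ndarray
    band_masks: list
    background: float
    pixel_size_um: float


def render_calibration_targets(
    params: ImageParams,
    step_ods=None,
    band_width_px: int = 48,
    height_px: int = 256,
    gradient_on_blank: bool = False,
) -> CalibrationTargets:
    """Render an 11-step linear density filter and a blank field.

    The stepped image holds homogeneous vertical bands of intensity
    I0 * 10**(-OD_k) (+ Gaussian noise); nominal ODs are returned as
    metadata together with the band masks.  Images are float count fields;
    quantization is left to the writer so that noise-free targets are exact.
    """
    rng = np.random.default_rng(params.seed)
    if step_ods is None:
        step_ods = np.linspace(0.1, 1.1, 11)
    step_ods = np.asarray(step_ods, dtype=float)
    if np.any(np.diff(step_ods) <= 0):
        raise ValidationError("step ODs must be strictly increasing")
    nbands = len(step_ods)
    width = nbands * band_width_px
    stepped = np.empty((height_px, width), dtype=np.float64)
    band_masks = []
    for k, odk in enumerate(step_ods):
        sl = slice(k * band_width_px, (k + 1) * band_width_px)
        stepped[:, sl] = params.background * 10.0 ** (-odk)
        m = np.zeros((height_px, width), dtype=bool)
        m[:, sl] = True
        band_masks.append(m)
    if params.noise_sd > 0:
        stepped = stepped + rng.normal(0.0, params.noise_sd, stepped.shape)

    blank = np.full((height_px, width), params.background, dtype=np.float64)
    if gradient_on_blank and params.gradient_amplitude:
        cols = np.arange(width, dtype=float)
        blank *= 1.0 + params.gradient_amplitude * (cols / (width - 1) - 0.5)
    if params.noise_sd > 0:
        blank = blank + rng.normal(0.0, params.noise_sd, blank.shape)
    return CalibrationTargets(
        stepped, blank, step_ods, band_masks, params.background, params.pixel_size_um
    )


def simulate_stability_trace(
    od_plateau: float = 0.5,
    tau_min: float = 5.0,
    t_max_min: float = 30.0,
    step_min: float = 2.0,
    noise_sd: float = 0.0005,
    seed: int = 0,
):
    """Exponential lamp warm-up trace of mean OD vs time (minutes).

    Emulates the drift of the mean optical-density signal after switching on
    a stabilized light source; with the default stability-test settings
    (window of 3 samples, tolerance 0.03 OD) the trace stabilizes at 12 min.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, t_max_min + step_min / 2.0, step_min)
    v = od_plateau * (1.0 - np.exp(-t / tau_min))
    if noise_sd > 0:
        v = v + rng.normal(0.0, noise_sd, t.shape)
    return list(zip(t.tolist(), v.tolist()))


# ---------------------------------------------------------------------------
# Flow-cytometry histogram simulation
# ---------------------------------------------------------------------------

def simulate_fcm_histogram(
    standard_2C: float,
    sample_2C: float,
    cv_standard: float,
    cv_sample: float,
    n_nuclei: int = 10_000,
    n_channels: int = 1024,
    seed: int = 0,
    standard_channel: float = 200.0,
    debris_fraction: float = 0.0,
) -> FCMHistogram:
    """Two-peak G0/G1 histogram from a Gaussian mixture.

    Component means are proportional to the two 2C values, scaled so the
    standard lands at ``standard_channel``; component sds are mean*CV/100.
    An optional uniform debris floor occupies ``debris_fraction`` of the
    events.  When the peak means are closer than twice the wider sd the
    metadata carries ``overlap_warning=True``.
    """
    if cv_standard <= 0 or cv_sample <= 0:
        raise ValidationError("CVs must be positive")
    if n_channels < 256:
        raise ValidationError("need at least 256 channels")
    rng = np.random.default_rng(seed)
    scale = standard_channel / standard_2C
    mean_std = standard_2C * scale
    mean_samp = sample_2C * scale
    sd_std = mean_std * cv_standard / 100.0
    sd_samp = mean_samp * cv_sample / 100.0
    n_debris = int(round(debris_fraction * n_nuclei))
    n_signal = n_nuclei - n_debris
    n_std = n_signal // 2
    n_samp = n_signal - n_std
    draws = np.concatenate(
        [
            rng.normal(mean_std, sd_std, n_std),
            rng.normal(mean_samp, sd_samp, n_samp),
            rng.uniform(0, n_channels, n_debris),
        ]
    )
    ch = np.clip(np.rint(draws).astype(int), 0, n_channels - 1)
    counts = np.bincount(ch, minlength=n_channels)
    overlap = abs(mean_samp - mean_std) < 2.0 * max(sd_std, sd_samp)
    meta = {
        "standard_2C_pg": standard_2C,
        "sample_2C_pg": sample_2C,
        "standard_channel": mean_std,
        "sample_channel": mean_samp,
        "overlap_warning": bool(overlap),
    }
    return FCMHistogram(np.arange(n_channels), counts, meta)
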