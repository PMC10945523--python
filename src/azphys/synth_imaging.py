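"""Synthetic four-channel STED/confocal fields with full ground truth.

The scene emulates the stratum-lucidum imagery the quantification
pipeline is built for: large VGLUT1-positive mossy-fiber boutons
(irregular unions of ellipses) containing several active zones (disks
with log-normal area), plus a set of small VGLUT1 blobs below the
terminal-size filter.  Each AZ carries Munc13-1 clusters (zero-truncated
Poisson count) on a diffuse Munc13-1 pedestal, Cav clusters offset from
Munc13-1 centroids by a programmed distance (default 61 nm, Gaussian
jitter on the magnitude, random direction), and an apposed PSD-95 punctum.
STED channels are blurred with a ~50 nm FWHM PSF, confocal channels with
~250 nm, then Poisson/Gaussian noise and 16-bit quantization are applied.

Design constraints the generator enforces so that its programmed values
are recoverable by the stated pipeline:

* Munc13-1 clusters within an AZ keep >= ~110 nm pairwise separation.
* A Cav cluster's offset direction is chosen so its *parent* Munc13-1
  cluster is its nearest one -- the drawn offset magnitude IS the true
  nearest-neighbor distance.
* Cav clusters keep >= ~100 nm pairwise separation (relaxed progressively
  when geometry is tight, never below the deconvolution resolution).

Every random draw flows from one seeded generator; rendering the same
(params, condition, seed) twice is bit-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.optimize import brentq

from .errors import GenerationError, InvalidParameterError
from .params import ImageSceneParams

__all__ = [
    "StedImageSet",
    "SyntheticGroundTruth",
    "render_sted_field",
    "save_imageset",
    "load_imageset",
    "zero_truncated_poisson",
]

CHANNEL_ORDER = ("munc13", "cav", "vglut1", "psd95")


@dataclass
class StedImageSet:
    """Registered four-channel field (uint16), 2D, shared pixel grid."""

    munc13: np.ndarray
    cav: np.ndarray
    vglut1: np.ndarray
    psd95: np.ndarray
    pixel_nm: float
    field_id: str = ""
    animal_id: str = ""
    genotype: str = "WT"
    cav_label: str = "Cav2.1"
    saturated: bool = False

    def __post_init__(self):
        shapes = {getattr(self, c).shape for c in CHANNEL_ORDER}
        if len(shapes) != 1:
            raise InvalidParameterError("channels must share one shape")
        if self.pixel_nm <= 0:
            raise InvalidParameterError("pixel_nm must be > 0")

    def channel(self, name: str) -> np.ndarray:
        return getattr(self, name)

    @property
    def shape(self):
        return self.munc13.shape


@dataclass
class SyntheticGroundTruth:
    """Generator parameters plus per-object annotations.

    azs: one dict per AZ with keys center_px (row, col), radius_px,
    terminal, in_small_terminal, munc_centroids_px, cav_centroids_px,
    cav_integrals, munc_integrals, total_cav_intensity, nnds_nm,
    n_cav_clusters, n_munc_clusters.
    """

    params: dict
    condition: str
    seed: int
    terminals: list
    azs: list
    programmed_sums: dict
    saturated: bool = False

    def az_centers(self) -> np.ndarray:
        return np.array([a["center_px"] for a in self.azs], float)

    def to_json(self) -> str:
        def default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            raise TypeError(type(o))
        return json.dumps(self.__dict__, default=default, indent=1)


# ---------------------------------------------------------------------------
# distribution helpers
# ---------------------------------------------------------------------------

def _ztp_lambda(mean: float) -> float:
    """Poisson rate whose zero-truncated mean equals ``mean``."""
    if mean <= 1.0:
        raise InvalidParameterError("zero-truncated Poisson mean must exceed 1")
    f = lambda lam: lam / (1.0 - np.exp(-lam)) - mean
    return brentq(f, 1e-9, 10.0 * mean)


def zero_truncated_poisson(rng: np.random.Generator, mean: float,
                           size: int | None = None):
    """Sample counts >= 1 with the given (truncated) mean."""
    lam = _ztp_lambda(mean)
    n = 1 if size is None else size
    out = np.empty(n, dtype=int)
    for i in range(n):
        k = 0
        while k == 0:
            k = rng.poisson(lam)
        out[i] = k
    return int(out[0]) if size is None else out


def _gamma_intensity(rng, mean, shape):
    return float(rng.gamma(shape, mean / shape))


def _median_az_total(count_mean: float, gamma_shape: float,
                     mean_intensity: float) -> float:
    """Median of the per-AZ total cluster intensity: a zero-truncated
    Poisson number of Gamma(shape) clusters (analytic mixture CDF)."""
    from scipy import stats as sps

    lam = _ztp_lambda(count_mean)
    ns = np.arange(1, 80)
    pn = sps.poisson.pmf(ns, lam)
    pn = pn / pn.sum()
    theta = mean_intensity / gamma_shape

    def cdf(x):
        return float(np.sum(pn * sps.gamma.cdf(x, gamma_shape * ns,
                                               scale=theta)))

    return brentq(lambda x: cdf(x) - 0.5, 1e-9,
                  mean_intensity * count_mean * 100)


def ko_cluster_scale(scene: ImageSceneParams) -> float:
    """Per-cluster Cav intensity factor for the KO condition.

    ko_intensity_scale programs the *per-AZ total* median intensity ratio
    KO/WT (the quantity the pipeline measures).  Because the KO also
    draws fewer clusters per AZ, the per-cluster factor is calibrated so
    the programmed per-AZ ratio comes out: c = ratio * median(S_WT) /
    median(S_KO at unit scale)."""
    if scene.ko_intensity_scale == 1.0 and (
            scene.cav_clusters_per_az_mean_ko
            == scene.cav_clusters_per_az_mean_wt):
        return 1.0
    med_wt = _median_az_total(scene.cav_clusters_per_az_mean_wt,
                              scene.intensity_gamma_shape,
                              scene.cluster_intensity)
    med_ko = _median_az_total(scene.cav_clusters_per_az_mean_ko,
                              scene.intensity_gamma_shape,
                              scene.cluster_intensity)
    return scene.ko_intensity_scale * med_wt / med_ko


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _disk_mask(shape, center, radius):
    r0 = int(np.floor(center[0] - radius - 1))
    r1 = int(np.ceil(center[0] + radius + 2))
    c0 = int(np.floor(center[1] - radius - 1))
    c1 = int(np.ceil(center[1] + radius + 2))
    r0, c0 = max(r0, 0), max(c0, 0)
    r1, c1 = min(r1, shape[0]), min(c1, shape[1])
    rr, cc = np.mgrid[r0:r1, c0:c1]
    m = (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2
    return (slice(r0, r1), slice(c0, c1)), m


def _add_disk(img, center, radius, value):
    sl, m = _disk_mask(img.shape, center, radius)
    img[sl][m] += value


def _render_terminal_mask(shape, center, r0, rng):
    """Union of 2-4 overlapping ellipses around ``center``."""
    k = int(rng.integers(2, 5))
    mask = np.zeros(shape, bool)
    for _ in range(k):
        a = r0 * rng.uniform(0.65, 1.05)
        b = r0 * rng.uniform(0.65, 1.05)
        theta = rng.uniform(0, np.pi)
        cy = center[0] + rng.uniform(-0.45, 0.45) * r0
        cx = center[1] + rng.uniform(-0.45, 0.45) * r0
        ext = max(a, b) + 2
        sl, _ = _disk_mask(shape, (cy, cx), ext)
        rr, cc = np.mgrid[sl[0], sl[1]]
        dy, dx = rr - cy, cc - cx
        u = (dx * np.cos(theta) + dy * np.sin(theta)) / a
        v = (-dx * np.sin(theta) + dy * np.cos(theta)) / b
        mask[sl] |= u**2 + v**2 <= 1.0
    return mask


def _add_gaussian_spot(img, center, sigma_px, integral):
    """Add an isotropic Gaussian spot normalised to the exact integral."""
    ext = max(5.0 * sigma_px, 3.0)
    sl, _ = _disk_mask(img.shape, center, ext)
    rr, cc = np.mgrid[sl[0], sl[1]]
    g = np.exp(-((rr - center[0]) ** 2 + (cc - center[1]) ** 2)
               / (2.0 * sigma_px**2))
    s = g.sum()
    if s <= 0:
        raise GenerationError("spot fell outside the field")
    img[sl] += g * (integral / s)


# ---------------------------------------------------------------------------
# placement
# ---------------------------------------------------------------------------

def _place_terminals(scene: ImageSceneParams, rng):
    shape = (scene.field_px, scene.field_px)
    specs = ([("large", scene.terminal_area_um2)] * scene.n_terminals
             + [("small", scene.small_terminal_area_um2)]
             * scene.n_small_terminals)
    placed = []   # (center, bound_radius, kind, mask)
    for kind, area_um2 in specs:
        area_px = area_um2 * 1e6 / scene.pixel_nm**2
        r0 = np.sqrt(area_px / np.pi)
        rb = (1.6 if kind == "large" else 1.1) * r0
        margin = rb + 5
        if 2 * margin >= scene.field_px:
            raise GenerationError(
                f"field of {scene.field_px} px cannot hold a terminal of "
                f"{area_um2} um^2 at {scene.pixel_nm} nm/px")
        ok = False
        for _ in range(200):
            c = rng.uniform(margin, scene.field_px - margin, size=2)
            if all(np.hypot(*(c - p[0])) >= rb + p[1] + 15
                   for p in placed):
                ok = True
                break
        if not ok:
            raise GenerationError(
                "could not place non-overlapping terminals: reduce "
                "n_terminals or terminal_area_um2, or enlarge field_px")
        if kind == "large":
            mask = _render_terminal_mask(shape, c, r0, rng)
        else:
            mask = np.zeros(shape, bool)
            sl, m = _disk_mask(shape, c, r0)
            mask[sl] |= m
        placed.append((c, rb, kind, mask))
    return placed


def _sample_az_center(term_edt, r_az, existing, rng, sep_px):
    """Random pixel at least r_az + 2 inside the terminal, separated from
    previously placed AZs; ``term_edt`` is the terminal's Euclidean
    distance transform."""
    coords = np.argwhere(term_edt > r_az + 2)
    if coords.size == 0:
        return None
    for _ in range(100):
        c = coords[rng.integers(len(coords))].astype(float)
        if all(np.hypot(*(c - e[0])) >= r_az + e[1] + sep_px
               for e in existing):
            return c
    return None


def _place_munc_clusters(center, r_az, n, rng, min_sep_px):
    """Cluster centroids inside the AZ disk with pairwise separation."""
    sep = min_sep_px
    for _relax in range(6):
        pts = []
        budget = 300
        r_max = max(r_az - 3.0, 2.0)
        while len(pts) < n and budget > 0:
            budget -= 1
            rho = r_max * np.sqrt(rng.uniform())
            th = rng.uniform(0, 2 * np.pi)
            p = center + rho * np.array([np.sin(th), np.cos(th)])
            if all(np.hypot(*(p - q)) >= sep for q in pts):
                pts.append(p)
        if len(pts) == n:
            return pts
        sep *= 0.85
    return pts   # best effort; realized count recorded in truth


def _place_cav_clusters(center, r_az, munc_pts, n, dist_px, jitter_px,
                        rng, min_sep_px):
    """Offset Cav centroids so the parent Munc13-1 cluster is nearest.

    Parents rotate through the Munc13-1 clusters; when a parent's
    neighbourhood is crowded, other parents are tried before the pairwise
    Cav separation is relaxed (floor: 8 px = 80 nm, the two-point
    resolution the deconvolution step restores)."""
    munc = np.asarray(munc_pts)
    order = rng.permutation(len(munc_pts))
    pts, nnd_px = [], []
    # keep Cav interior to the AZ so its mask intersects the binarized
    # AZ component; use radial slack first, and only then relax the
    # pairwise separation (sub-resolution spacing merges clusters)
    stages = [(min_sep_px, max(r_az - 4.0, 0.5 * r_az)),
              (min_sep_px, max(r_az - 2.0, 0.5 * r_az)),
              (min_sep_px, r_az),
              (min_sep_px, r_az + 2.0),
              (0.9 * min_sep_px, r_az + 2.0),
              (max(0.8 * min_sep_px, 8.0), r_az + 2.0),
              (8.0, r_az + 4.0),
              (6.0, r_az + 4.0)]
    for k in range(n):
        placed = None
        # the offset magnitude is drawn once per cluster -- redrawing it
        # per attempt would bias accepted distances low in tight geometry
        d = max(rng.normal(dist_px, jitter_px), 2.0)
        for stage_i, (sep, r_place) in enumerate(stages):
            if stage_i == len(stages) - 1:
                # last resort: accept a fresh distance rather than drop
                # the cluster (a dropped cluster distorts the programmed
                # count distribution more than a redrawn offset)
                d = max(rng.normal(dist_px, jitter_px), 2.0)
            parent_seq = ([order[k % len(order)]]
                          + list(rng.permutation(len(munc_pts))))
            for pi in parent_seq:
                parent = munc[pi]
                others = np.delete(munc, pi, axis=0)
                for _attempt in range(80):
                    th = rng.uniform(0, 2 * np.pi)
                    p = parent + d * np.array([np.sin(th), np.cos(th)])
                    if np.hypot(*(p - center)) > r_place:
                        continue
                    if (others.size
                            and np.min(np.hypot(*(p - others).T)) <= d + 0.5):
                        continue   # parent must stay the nearest Munc13-1
                    if all(np.hypot(*(p - q)) >= sep for q in pts):
                        placed = p
                        break
                if placed is not None:
                    break
            if placed is not None:
                break
        if placed is None:
            continue   # geometrically impossible; realized count in truth
        pts.append(placed)
        nnd_px.append(float(np.min(np.hypot(*(placed - munc).T))))
    return pts, nnd_px


# ---------------------------------------------------------------------------
# main renderer
# ---------------------------------------------------------------------------

def render_sted_field(scene: ImageSceneParams, condition: str = "WT",
                      seed: int = 0, field_id: str = "",
                      animal_id: str = ""):
    """Render one field; returns (StedImageSet, SyntheticGroundTruth)."""
    if condition not in ("WT", "KO"):
        raise InvalidParameterError("condition must be WT or KO")
    rng = np.random.default_rng(seed)
    px = scene.pixel_nm
    shape = (scene.field_px, scene.field_px)

    terminals = _place_terminals(scene, rng)

    munc_img = np.full(shape, float(scene.background_sted))
    munc_pedestal_img = np.zeros(shape)
    cav_img = np.full(shape, float(scene.background_sted))
    vglut_img = np.full(shape, float(scene.background_confocal))
    psd_img = np.full(shape, float(scene.background_confocal))
    sums = {c: float(getattr(scene, "background_sted"
                             if c in ("munc13", "cav")
                             else "background_confocal"))
            * scene.field_px**2 for c in CHANNEL_ORDER}

    term_records = []
    for i, (c, _rb, kind, mask) in enumerate(terminals):
        vglut_img[mask] += scene.vglut_intensity
        sums["vglut1"] += scene.vglut_intensity * int(mask.sum())
        term_records.append({"center_px": c.tolist(), "kind": kind,
                             "area_px": int(mask.sum()),
                             "area_um2": int(mask.sum()) * px**2 / 1e6})

    cav_mean = (scene.cav_clusters_per_az_mean_ko if condition == "KO"
                else scene.cav_clusters_per_az_mean_wt)
    cav_scale = ko_cluster_scale(scene) if condition == "KO" else 1.0
    dist_px = scene.cav_munc_distance_nm / px
    jitter_px = scene.cav_munc_jitter_nm / px
    sigma_px = scene.cluster_sigma_nm / px
    munc_sigma_px = scene.munc_cluster_sigma_nm / px

    azs = []
    for ti, (tc, _rb, kind, tmask) in enumerate(terminals):
        if kind == "large":
            n_az = rng.poisson(scene.az_per_terminal_mean)
        else:
            n_az = 1
        term_edt = ndimage.distance_transform_edt(tmask)
        placed_here = []
        for _ in range(n_az):
            area_nm2 = np.exp(rng.normal(np.log(scene.az_area_um2 * 1e6),
                                         scene.az_area_sigma_log))
            r_az = np.sqrt(area_nm2 / np.pi) / px
            c_az = _sample_az_center(term_edt, r_az, placed_here, rng,
                                     sep_px=150.0 / px)
            if c_az is None:
                continue   # terminal full; realized count is in truth
            placed_here.append((c_az, r_az))

            n_munc = zero_truncated_poisson(rng, scene.munc_clusters_per_az_mean)
            munc_pts = _place_munc_clusters(c_az, r_az, n_munc, rng,
                                            min_sep_px=110.0 / px)
            if not munc_pts:
                continue
            n_cav = zero_truncated_poisson(rng, cav_mean)
            cav_pts, nnd_px = _place_cav_clusters(
                c_az, r_az, munc_pts, n_cav, dist_px, jitter_px, rng,
                min_sep_px=100.0 / px)

            if scene.munc_pedestal > 0:
                r_ped = r_az + scene.pedestal_margin_nm / px
                _add_disk(munc_pedestal_img, c_az, r_ped, scene.munc_pedestal)
                _sl, _m = _disk_mask(shape, c_az, r_ped)
                sums["munc13"] += scene.munc_pedestal * int(_m.sum())

            def spot_sigma(w, mean, base):
                # cluster footprint grows with content (more channels
                # spread wider), which also keeps peak heights comparable
                if not scene.cluster_sigma_scales:
                    return base
                return base * np.clip(np.sqrt(w / mean), 0.6, 2.0)

            munc_ints, cav_ints = [], []
            for p in munc_pts:
                w = _gamma_intensity(rng, scene.munc_cluster_intensity,
                                     scene.intensity_gamma_shape)
                _add_gaussian_spot(munc_img, p,
                                   spot_sigma(w, scene.munc_cluster_intensity,
                                              munc_sigma_px),
                                   w)
                sums["munc13"] += w
                munc_ints.append(w)
            for p in cav_pts:
                w = _gamma_intensity(rng, scene.cluster_intensity,
                                     scene.intensity_gamma_shape)
                s = spot_sigma(w, scene.cluster_intensity, sigma_px)
                w *= cav_scale
                _add_gaussian_spot(cav_img, p, s, w)
                sums["cav"] += w
                cav_ints.append(w)

            psd_center = c_az + rng.normal(0, 3.0, size=2)
            _add_gaussian_spot(psd_img, psd_center, 50.0 / px,
                               scene.psd_intensity)
            sums["psd95"] += scene.psd_intensity

            azs.append({
                "center_px": c_az.tolist(),
                "radius_px": float(r_az),
                "terminal": ti,
                "in_small_terminal": kind == "small",
                "munc_centroids_px": [p.tolist() for p in munc_pts],
                "cav_centroids_px": [p.tolist() for p in cav_pts],
                "munc_integrals": munc_ints,
                "cav_integrals": cav_ints,
                "total_cav_intensity": float(np.sum(cav_ints)),
                "n_munc_clusters": len(munc_pts),
                "n_cav_clusters": len(cav_pts),
                "nnds_nm": [d * px for d in nnd_px],
            })

    # soft-edged Munc13-1 pedestal: the AZ protein carpet has no sharp
    # rim (and a hard edge would ring under deconvolution)
    if scene.pedestal_taper_nm > 0:
        munc_pedestal_img = ndimage.gaussian_filter(
            munc_pedestal_img, scene.pedestal_taper_nm / px)
    munc_img = munc_img + munc_pedestal_img

    # PSF blur
    def blur(img, fwhm_nm):
        if fwhm_nm <= 0:
            return img
        return ndimage.gaussian_filter(img, fwhm_nm / 2.3548 / px)

    munc_img = blur(munc_img, scene.psf_fwhm_sted_nm)
    cav_img = blur(cav_img, scene.psf_fwhm_sted_nm)
    vglut_img = blur(vglut_img, scene.psf_fwhm_confocal_nm)
    psd_img = blur(psd_img, scene.psf_fwhm_confocal_nm)

    # noise, then 16-bit quantization (clip + flag)
    def noisify(img):
        if scene.noise_model in ("poisson", "both"):
            img = rng.poisson(np.maximum(img, 0)).astype(float)
        if scene.noise_model in ("gaussian", "both"):
            img = img + rng.normal(0, scene.gaussian_noise_sd, img.shape)
        return img

    saturated = False
    chans = {}
    for name, img in (("munc13", munc_img), ("cav", cav_img),
                      ("vglut1", vglut_img), ("psd95", psd_img)):
        img = noisify(img)
        if img.max() > 65535:
            saturated = True
        chans[name] = np.clip(np.rint(img), 0, 65535).astype(np.uint16)

    imgset = StedImageSet(chans["munc13"], chans["cav"], chans["vglut1"],
                          chans["psd95"], px, field_id=field_id,
                          animal_id=animal_id, genotype=condition,
                          saturated=saturated)
    truth = SyntheticGroundTruth(scene.to_dict(), condition, seed,
                                 term_records, azs, sums, saturated)
    return imgset, truth


# ---------------------------------------------------------------------------
# I/O: multi-page TIFF + JSON sidecar
# ---------------------------------------------------------------------------

def save_imageset(imgset: StedImageSet, path, truth=None):
    """Write a 4-page TIFF (Munc13-1, Cav, VGLUT1, PSD-95) with the pixel
    size in the resolution tags, plus a JSON sidecar (metadata and, when
    given, the ground truth)."""
    import tifffile

    stack = np.stack([imgset.channel(c) for c in CHANNEL_ORDER])
    px_per_cm = 1e7 / imgset.pixel_nm
    tifffile.imwrite(str(path), stack, photometric="minisblack",
                     resolution=(px_per_cm, px_per_cm),
                     resolutionunit="CENTIMETER")
    meta = {"pixel_nm": imgset.pixel_nm, "channels": list(CHANNEL_ORDER),
            "field_id": imgset.field_id, "animal_id": imgset.animal_id,
            "genotype": imgset.genotype, "cav_label": imgset.cav_label,
            "saturated": imgset.saturated}
    if truth is not None:
        meta["ground_truth"] = json.loads(truth.to_json())
    sidecar = str(path) + ".json"
    with open(sidecar, "w") as fh:
        json.dump(meta, fh, indent=1)
    return sidecar


def load_imageset(path):
    """Read a field written by :func:`save_imageset`."""
    import tifffile

    stack = tifffile.imread(str(path))
    with open(str(path) + ".json") as fh:
        meta = json.load(fh)
    return StedImageSet(*[stack[i] for i in range(4)],
                        pixel_nm=meta["pixel_nm"],
                        field_id=meta.get("field_id", ""),
                        animal_id=meta.get("animal_id", ""),
                        genotype=meta.get("genotype", "WT"),
                        cav_label=meta.get("cav_label", "Cav2.1"),
                        saturated=meta.get("saturated", False))
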