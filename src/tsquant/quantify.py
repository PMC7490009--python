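"""Single-peptide intensity calibration and nascent-chain counting.

The unit of measurement is the integrated intensity of one released, fully
synthesized SunTag array (the "idealized single peptide", I_single).  Free
single peptides are protein-channel spots in the cytoplasm away from every
mRNA; after robust outlier rejection their mean integrated intensity defines
I_single.  Each mRNA's translation site is then quantified by a Gaussian fit
seeded at the brightest voxel of an 11 x 11 x-y box around the mRNA, and its
nascent-chain count is N = I_ts / I_single.  Sites failing shape, intensity
or distance filters carry I_ts = 0; mRNAs with N < 1 are classified as
unassociated with SunTag signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .detect import CandidatePeak, Spot, fit_spot
from .geometry import ImageStack


class CalibrationError(RuntimeError):
    """Raised when too few free-peptide spots survive to define I_single."""


@dataclass(frozen=True)
class SinglePeptideCalibration:
    """The intensity of one fully synthesized SunTag array.

    ``i_single`` is the mean background-subtracted integrated intensity of
    the surviving free-peptide spots; ``sigma_xy_med``/``sigma_z_med`` are
    their median fitted widths (voxel units), reused as the shape reference
    for translation-site filtering.
    """

    i_single: float
    n_spots_used: int
    cv: float
    sigma_xy_med: float
    sigma_z_med: float


@dataclass
class TranslationSite:
    """Per-mRNA quantification result.

    ``i_ts`` is 0 whenever the site fit failed any filter; ``n_chains`` is
    ``i_ts / i_single``; ``associated`` is True iff ``n_chains >= 1``.
    ``distance_px`` is the x-y distance from the fitted site center to the
    mRNA center (NaN when no fit was attempted or retained).
    """

    mrna_id: int
    i_ts: float
    n_chains: float
    distance_px: float
    associated: bool


@dataclass(frozen=True)
class SiteFitParams:
    """Translation-site search/fit settings.

    The search box is ``box_xy`` x ``box_xy`` pixels in x-y (the 11 x 11
    bounding box) over the mRNA's z plane +/- ``z_half`` planes.  The fitted
    center must land within ``max_distance_px`` (x-y) of the mRNA, and the
    fitted sigmas within [sigma_lo_factor, sigma_hi_factor] times the
    calibration spots' median sigmas.
    """

    box_xy: int = 11
    z_half: int = 2
    max_distance_px: float = 3.0
    sigma_lo_factor: float = 0.5
    sigma_hi_factor: float = 3.0
    fit_window: tuple[int, int, int] = (5, 11, 11)


def select_free_peptides(
    protein_spots: list[Spot],
    mrna_spots: list[Spot],
    cyto_mask: np.ndarray,
    exclusion_radius_px: float,
) -> list[Spot]:
    """Protein spots in the cytoplasm, away from every mRNA.

    A spot qualifies when its nearest x-y pixel lies in the cytoplasm mask
    and its x-y distance to every mRNA spot exceeds ``exclusion_radius_px``
    — i.e. it cannot be a translation site.
    """
    cyto = np.asarray(cyto_mask, dtype=bool)
    n_y, n_x = cyto.shape
    if mrna_spots:
        my = np.array([s.y0 for s in mrna_spots])
        mx = np.array([s.x0 for s in mrna_spots])
    out = []
    for s in protein_spots:
        iy, ix = int(round(s.y0)), int(round(s.x0))
        if not (0 <= iy < n_y and 0 <= ix < n_x and cyto[iy, ix]):
            continue
        if mrna_spots:
            d2 = (my - s.y0) ** 2 + (mx - s.x0) ** 2
            if d2.min() <= exclusion_radius_px**2:
                continue
        out.append(s)
    return out


def _mad_inliers(values: np.ndarray, k: float = 3.0) -> np.ndarray:
    """Boolean mask of values within median +/- k*MAD (all True if MAD=0)."""
    med = np.median(values)
    mad = np.median(np.abs(values - med))
    if mad == 0:
        return np.ones(len(values), dtype=bool)
    return np.abs(values - med) <= k * mad


def calibrate_single_peptide(
    free_spots: list[Spot],
    min_spots: int = 5,
    k_mad: float = 3.0,
) -> SinglePeptideCalibration:
    """Average free-peptide spots into the idealized single-peptide unit.

    Spots outside median +/- ``k_mad``*MAD in integrated intensity or in
    either fitted sigma are dropped (automated stand-in for by-eye curation
    of the free-peptide population); I_single is the mean integrated
    intensity of the survivors.
    """
    if len(free_spots) < min_spots:
        raise CalibrationError(
            f"calibration needs >= {min_spots} free-peptide spots; got {len(free_spots)}"
        )
    ii = np.array([s.integrated_intensity for s in free_spots])
    sxy = np.array([s.sigma_xy for s in free_spots])
    sz = np.array([s.sigma_z for s in free_spots])
    keep = _mad_inliers(ii, k_mad) & _mad_inliers(sxy, k_mad) & _mad_inliers(sz, k_mad)
    if keep.sum() < min_spots:
        raise CalibrationError(
            f"only {int(keep.sum())} free-peptide spots survive outlier rejection "
            f"(minimum {min_spots})"
        )
    surv = ii[keep]
    i_single = float(surv.mean())
    if i_single <= 0:
        raise CalibrationError("non-positive single-peptide intensity")
    return SinglePeptideCalibration(
        i_single=i_single,
        n_spots_used=int(keep.sum()),
        cv=float(surv.std(ddof=1) / i_single) if keep.sum() > 1 else 0.0,
        sigma_xy_med=float(np.median(sxy[keep])),
        sigma_z_med=float(np.median(sz[keep])),
    )


def quantify_translation_site(
    protein_stack: ImageStack,
    mrna_spot: Spot,
    cal: SinglePeptideCalibration,
    params: SiteFitParams = SiteFitParams(),
    mrna_id: int = 0,
) -> TranslationSite:
    """Quantify the translation site of one mRNA in the protein channel.

    The brightest voxel inside the x-y box around the mRNA (within
    ``z_half`` planes of the mRNA's z) seeds a 3D Gaussian fit.  The site is
    retained only if the fit converged with positive amplitude, its sigmas
    sit inside the calibration-derived shape bounds, and the fitted center
    is within ``max_distance_px`` of the mRNA; any failure sets I_ts = 0.
    """
    data = np.asarray(protein_stack.data, dtype=float)
    n_z, n_y, n_x = data.shape
    half = params.box_xy // 2
    iz, iy, ix = int(round(mrna_spot.z0)), int(round(mrna_spot.y0)), int(round(mrna_spot.x0))
    zs = slice(max(0, iz - params.z_half), min(n_z, iz + params.z_half + 1))
    ys = slice(max(0, iy - half), min(n_y, iy + half + 1))
    xs = slice(max(0, ix - half), min(n_x, ix + half + 1))
    box = data[zs, ys, xs]

    def _empty(dist: float = np.nan) -> TranslationSite:
        return TranslationSite(mrna_id, 0.0, 0.0, dist, associated=False)

    if box.size == 0:
        return _empty()
    bz, by, bx = np.unravel_index(int(np.argmax(box)), box.shape)
    peak = CandidatePeak(zs.start + bz, ys.start + by, xs.start + bx, float(box[bz, by, bx]))
    spot = fit_spot(
        protein_stack,
        peak,
        window=params.fit_window,
        sigma_guess=(cal.sigma_xy_med, cal.sigma_z_med),
    )
    dist = float(np.hypot(spot.y0 - mrna_spot.y0, spot.x0 - mrna_spot.x0))
    shape_ok = (
        params.sigma_lo_factor * cal.sigma_xy_med <= spot.sigma_xy <= params.sigma_hi_factor * cal.sigma_xy_med
        and params.sigma_lo_factor * cal.sigma_z_med <= spot.sigma_z <= params.sigma_hi_factor * cal.sigma_z_med
    )
    if not (spot.ok and spot.amplitude > 0 and shape_ok and dist <= params.max_distance_px):
        return _empty(dist)
    i_ts = spot.integrated_intensity
    n = i_ts / cal.i_single
    return TranslationSite(mrna_id, float(i_ts), float(n), dist, associated=classify_association(n))


def classify_association(n_chains: float) -> bool:
    """Associated with SunTag signal iff the site holds >= 1 peptide unit."""
    return bool(n_chains >= 1.0)


def sites_to_frame(sites: list[TranslationSite]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "mrna_id": s.mrna_id,
                "i_ts": s.i_ts,
                "n_chains": s.n_chains,
                "distance_px": s.distance_px,
                "associated": s.associated,
            }
            for s in sites
        ],
        columns=["mrna_id", "i_ts", "n_chains", "distance_px", "associated"],
    )
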