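"""Synthetic two-channel smFISH-IF scene generator.

Emulates fixed-cell single-molecule FISH-IF acquisitions of a SunTag
translation reporter: the mRNA channel carries one diffraction-limited spot
per cytoplasmic mRNA; the protein channel carries a translation site of
integrated intensity ``k * i_single`` for every mRNA with ``k`` ribosome-
attached nascent chains, plus released single SunTag peptides of intensity
``i_single`` scattered through the cytoplasm.  Drug-condition presets set
the probability that an mRNA is translating and hence the per-cell fraction
of mRNAs colocalized with protein signal, which is the statistic the
downstream pipeline estimates.

Ground truth (positions, translating flags, nascent counts) is returned
alongside the rendered stacks so detection and quantification can be scored
exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import CellGeometry, ImageStack, default_geometry


@dataclass(frozen=True)
class ConditionPreset:
    """Drug-condition parameters for scene generation.

    Attributes
    ----------
    name : str
        Condition label.
    p_translating : float
        Probability an mRNA carries nascent chains (is "translating").
    nascent_mean_extra : float
        Poisson mean of additional nascent chains beyond the first on a
        translating mRNA: k = 1 + Poisson(nascent_mean_extra), so k >= 1
        whenever translating.
    free_peptide_density : float
        Expected number of released single peptides per cell (Poisson).
    """

    name: str
    p_translating: float
    nascent_mean_extra: float = 4.0
    free_peptide_density: float = 20.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_translating <= 1.0:
            raise ValueError("p_translating must be in [0, 1]")
        if self.nascent_mean_extra < 0 or self.free_peptide_density < 0:
            raise ValueError("rates must be nonnegative")


#: Condition table: the translating probabilities are the per-cell mean
#: colocalized fractions reported for untreated cells, 5 min puromycin,
#: emetine pre-treatment + puromycin, and anisomycin pre-treatment +
#: puromycin respectively.
PRESETS: dict[str, ConditionPreset] = {
    "untreated": ConditionPreset("untreated", 0.63),
    "puromycin": ConditionPreset("puromycin", 0.03),
    "emetine_puromycin": ConditionPreset("emetine_puromycin", 0.05),
    "anisomycin": ConditionPreset("anisomycin", 0.50),
}


@dataclass(frozen=True)
class PSFModel:
    """Isotropic-in-xy anisotropic Gaussian point-spread function (nm)."""

    sigma_xy_nm: float = 100.0
    sigma_z_nm: float = 350.0

    def __post_init__(self) -> None:
        if self.sigma_xy_nm <= 0 or self.sigma_z_nm <= 0:
            raise ValueError("PSF widths must be positive")
        if self.sigma_z_nm < self.sigma_xy_nm:
            raise ValueError("sigma_z must be >= sigma_xy")

    def sigma_voxels(self, geometry: CellGeometry) -> tuple[float, float]:
        """(sigma_xy, sigma_z) in voxel units for a given sampling."""
        return self.sigma_xy_nm / geometry.dx_nm, self.sigma_z_nm / geometry.dz_nm


@dataclass(frozen=True)
class NoiseModel:
    """Camera model: Poisson shot noise through a gain, plus read noise.

    ``gain`` converts counts to detected photons (photons = counts / gain);
    gain = 0 disables shot noise entirely, and read_sigma = 0 disables read
    noise, which makes rendering deterministic for tests.
    """

    background: float = 100.0
    gain: float = 1.0
    read_sigma: float = 2.0

    def __post_init__(self) -> None:
        if self.background < 0 or self.gain < 0 or self.read_sigma < 0:
            raise ValueError("noise parameters must be nonnegative")

    def apply(self, clean: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        out = np.asarray(clean, dtype=float)
        if self.gain > 0:
            out = self.gain * rng.poisson(out / self.gain).astype(float)
        if self.read_sigma > 0:
            out = out + rng.normal(0.0, self.read_sigma, size=out.shape)
        return out


MRNA_COLUMNS = ["mrna_id", "z", "y", "x", "translating", "k", "intensity"]
FREE_COLUMNS = ["peptide_id", "z", "y", "x", "intensity_units"]


@dataclass
class GroundTruth:
    """Per-emitter generating truth for one synthetic cell.

    ``mrna`` has one row per mRNA (continuous position in voxel units,
    translating flag, nascent count k, mRNA-channel integrated intensity in
    counts).  ``free_peptides`` has one row per released single peptide
    (position, intensity in single-peptide units; released arrays are fully
    synthesized, so exactly 1.0).
    """

    mrna: pd.DataFrame
    free_peptides: pd.DataFrame

    def __post_init__(self) -> None:
        m, f = self.mrna, self.free_peptides
        if list(m.columns) != MRNA_COLUMNS or list(f.columns) != FREE_COLUMNS:
            raise ValueError("ground-truth tables have unexpected columns")
        translating = m["translating"].to_numpy(dtype=bool)
        k = m["k"].to_numpy()
        if np.any(translating != (k >= 1)):
            raise ValueError("translating flag must equal (k >= 1)")

    def to_csv(self, mrna_path: str | Path, free_path: str | Path) -> None:
        self.mrna.to_csv(mrna_path, index=False)
        self.free_peptides.to_csv(free_path, index=False)

    @classmethod
    def from_csv(cls, mrna_path: str | Path, free_path: str | Path) -> "GroundTruth":
        m = pd.read_csv(mrna_path)
        f = pd.read_csv(free_path)
        if len(m) == 0:
            m = pd.DataFrame(columns=MRNA_COLUMNS)
        if len(f) == 0:
            f = pd.DataFrame(columns=FREE_COLUMNS)
        m = m.astype({"translating": bool}) if len(m) else m
        return cls(mrna=m[MRNA_COLUMNS], free_peptides=f[FREE_COLUMNS])


def _draw_positions(
    n: int,
    geometry: CellGeometry,
    rng: np.random.Generator,
    min_spacing_px: float,
    z_margin: float,
    existing_xy: np.ndarray | None = None,
) -> np.ndarray:
    """Uniform positions over the cytoplasm with a minimum x-y spacing.

    Dart throwing over cytoplasm pixels with sub-pixel jitter; spacing is
    enforced against both previously placed and ``existing_xy`` positions.
    Returns an (n, 3) array of (z, y, x) in voxel units.
    """
    cyto_yx = np.argwhere(geometry.cyto_mask)
    if len(cyto_yx) == 0:
        raise ValueError("geometry has an empty cytoplasm mask")
    n_z = geometry.shape[0]
    z_lo = min(z_margin, (n_z - 1) / 2.0)
    z_hi = max(n_z - 1 - z_margin, z_lo)

    placed_xy: list[np.ndarray] = [] if existing_xy is None else [np.asarray(existing_xy)]
    out = np.empty((n, 3), dtype=float)
    max_attempts = 200 * max(n, 1)
    attempts = 0
    i = 0
    while i < n:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"could not place {n} emitters with min spacing {min_spacing_px} px; "
                "cytoplasm too small or too crowded"
            )
        attempts += 1
        yx = cyto_yx[rng.integers(len(cyto_yx))] + rng.uniform(-0.5, 0.5, size=2)
        if min_spacing_px > 0 and placed_xy:
            prev = np.vstack(placed_xy)
            d2 = (prev[:, 0] - yx[0]) ** 2 + (prev[:, 1] - yx[1]) ** 2
            if d2.min() < min_spacing_px**2:
                continue
        z = rng.uniform(z_lo, z_hi)
        out[i] = (z, yx[0], yx[1])
        placed_xy.append(yx)
        i += 1
    return out


def sample_ground_truth(
    preset: ConditionPreset,
    geometry: CellGeometry,
    n_mrna: int,
    seed: int,
    min_spacing_px: float = 5.0,
    z_margin: float = 2.0,
    mrna_intensity_mean: float = 2000.0,
    mrna_intensity_cv: float = 0.2,
) -> GroundTruth:
    """Draw the generating truth for one cell.

    Each mRNA is independently translating with probability
    ``preset.p_translating``; translating mRNAs draw ``k = 1 + Poisson``
    nascent chains.  Positions are uniform over the cytoplasm with a minimum
    pairwise x-y spacing (also enforced between mRNAs and free peptides, so
    no two emitters blend into one detection).  mRNA-channel intensities are
    log-normal around ``mrna_intensity_mean``.
    """
    if n_mrna < 0:
        raise ValueError("n_mrna must be >= 0")
    rng = np.random.default_rng(seed)

    pos = _draw_positions(n_mrna, geometry, rng, min_spacing_px, z_margin)
    translating = rng.random(n_mrna) < preset.p_translating
    k = np.zeros(n_mrna, dtype=int)
    k[translating] = 1 + rng.poisson(preset.nascent_mean_extra, size=int(translating.sum()))

    # log-normal with the requested mean and coefficient of variation
    sig2 = np.log(1.0 + mrna_intensity_cv**2)
    mu = np.log(mrna_intensity_mean) - sig2 / 2.0
    intensity = rng.lognormal(mu, np.sqrt(sig2), size=n_mrna)

    mrna = pd.DataFrame(
        {
            "mrna_id": np.arange(n_mrna),
            "z": pos[:, 0],
            "y": pos[:, 1],
            "x": pos[:, 2],
            "translating": translating,
            "k": k,
            "intensity": intensity,
        }
    )

    n_free = rng.poisson(preset.free_peptide_density)
    fpos = _draw_positions(
        n_free, geometry, rng, min_spacing_px, z_margin, existing_xy=pos[:, 1:3]
    )
    free = pd.DataFrame(
        {
            "peptide_id": np.arange(n_free),
            "z": fpos[:, 0],
            "y": fpos[:, 1],
            "x": fpos[:, 2],
            "intensity_units": np.ones(n_free),
        }
    )
    return GroundTruth(mrna=mrna, free_peptides=free)


def add_gaussian_spot(
    data: np.ndarray,
    center: tuple[float, float, float],
    integrated: float,
    sigma_xy: float,
    sigma_z: float,
    extent_sigmas: float = 4.0,
) -> None:
    """Add a point-sampled 3D Gaussian of given integrated intensity in place.

    The amplitude is ``integrated / ((2*pi)**1.5 * sigma_xy**2 * sigma_z)``;
    rendering is truncated at ``extent_sigmas`` standard deviations.
    """
    z0, y0, x0 = center
    n_z, n_y, n_x = data.shape
    amp = integrated / ((2.0 * np.pi) ** 1.5 * sigma_xy**2 * sigma_z)
    rz, rxy = extent_sigmas * sigma_z, extent_sigmas * sigma_xy
    zs = slice(max(0, int(np.floor(z0 - rz))), min(n_z, int(np.ceil(z0 + rz)) + 1))
    ys = slice(max(0, int(np.floor(y0 - rxy))), min(n_y, int(np.ceil(y0 + rxy)) + 1))
    xs = slice(max(0, int(np.floor(x0 - rxy))), min(n_x, int(np.ceil(x0 + rxy)) + 1))
    zz = np.arange(zs.start, zs.stop, dtype=float)[:, None, None]
    yy = np.arange(ys.start, ys.stop, dtype=float)[None, :, None]
    xx = np.arange(xs.start, xs.stop, dtype=float)[None, None, :]
    data[zs, ys, xs] += amp * np.exp(
        -((yy - y0) ** 2 + (xx - x0) ** 2) / (2.0 * sigma_xy**2)
        - (zz - z0) ** 2 / (2.0 * sigma_z**2)
    )


def render_stack(
    gt: GroundTruth,
    geometry: CellGeometry,
    psf: PSFModel,
    noise: NoiseModel,
    i_single_true: float,
    seed: int,
) -> tuple[ImageStack, ImageStack]:
    """Render the (mRNA, protein) channel pair for one cell.

    Every mRNA renders one spot in the mRNA channel at its ground-truth
    intensity; every translating mRNA renders a protein-channel spot of
    integrated intensity ``k * i_single_true`` at the same position; every
    free peptide renders a protein-channel spot of ``i_single_true``.  The
    camera background and noise are applied last.
    """
    sxy, sz = psf.sigma_voxels(geometry)
    shape = geometry.shape
    mrna_clean = np.zeros(shape, dtype=float)
    prot_clean = np.zeros(shape, dtype=float)

    for row in gt.mrna.itertuples(index=False):
        add_gaussian_spot(mrna_clean, (row.z, row.y, row.x), row.intensity, sxy, sz)
        if row.k >= 1:
            add_gaussian_spot(prot_clean, (row.z, row.y, row.x), row.k * i_single_true, sxy, sz)
    for row in gt.free_peptides.itertuples(index=False):
        add_gaussian_spot(
            prot_clean, (row.z, row.y, row.x), row.intensity_units * i_single_true, sxy, sz
        )

    rng = np.random.default_rng(seed)
    mrna_data = noise.apply(mrna_clean + noise.background, rng)
    prot_data = noise.apply(prot_clean + noise.background, rng)
    kw = dict(dx_nm=geometry.dx_nm, dy_nm=geometry.dy_nm, dz_nm=geometry.dz_nm)
    return ImageStack(mrna_data, **kw), ImageStack(prot_data, **kw)


def cell_seed(master_seed: int, condition: str, cell_index: int) -> int:
    """Stable per-cell seed: independent of how many cells/conditions run."""
    import hashlib

    h = hashlib.sha256(f"{master_seed}:{condition}:{cell_index}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def generate_experiment(
    presets: list[ConditionPreset],
    n_cells_per_condition: int,
    seed: int,
    out_dir: str | Path,
    geometry: CellGeometry | None = None,
    psf: PSFModel | None = None,
    noise: NoiseModel | None = None,
    i_single_true: float = 1200.0,
    n_mrna_range: tuple[int, int] = (8, 30),
) -> pd.DataFrame:
    """Write a full multi-condition synthetic experiment to disk.

    Per cell: two TIFF stacks (one per channel), two ground-truth CSVs; one
    manifest row linking them.  Per-cell mRNA counts are uniform over
    ``n_mrna_range`` (inclusive), inside the downstream 6-35 inclusion
    filter.  Returns the manifest, also written as ``manifest.csv`` with a
    ``params.json`` sidecar echoing the generation parameters.
    """
    from .io import write_stack

    if n_cells_per_condition < 1:
        raise ValueError("n_cells_per_condition must be >= 1")
    geometry = geometry if geometry is not None else default_geometry()
    psf = psf if psf is not None else PSFModel()
    noise = noise if noise is not None else NoiseModel()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    rows = []
    for preset in presets:
        for i in range(n_cells_per_condition):
            cseed = cell_seed(seed, preset.name, i)
            rng = np.random.default_rng(cseed)
            n_mrna = int(rng.integers(n_mrna_range[0], n_mrna_range[1] + 1))
            gt = sample_ground_truth(preset, geometry, n_mrna, seed=cseed)
            mrna_stack, prot_stack = render_stack(
                gt, geometry, psf, noise, i_single_true, seed=cseed + 1
            )
            stem = f"{preset.name}_cell{i:03d}"
            paths = {
                "mrna_tiff": f"{stem}_mrna.tif",
                "protein_tiff": f"{stem}_protein.tif",
                "mrna_truth_csv": f"{stem}_truth_mrna.csv",
                "free_truth_csv": f"{stem}_truth_free.csv",
            }
            write_stack(mrna_stack, out_dir / paths["mrna_tiff"])
            write_stack(prot_stack, out_dir / paths["protein_tiff"])
            gt.to_csv(out_dir / paths["mrna_truth_csv"], out_dir / paths["free_truth_csv"])
            rows.append(
                {
                    "condition": preset.name,
                    "cell_index": i,
                    "seed": cseed,
                    "n_mrna": n_mrna,
                    **paths,
                }
            )

    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    params = {
        "seed": seed,
        "n_cells_per_condition": n_cells_per_condition,
        "presets": [vars(p) for p in presets],
        "i_single_true": i_single_true,
        "n_mrna_range": list(n_mrna_range),
        "geometry": {
            "shape": list(geometry.shape),
            "dx_nm": geometry.dx_nm,
            "dz_nm": geometry.dz_nm,
        },
        "psf": vars(psf),
        "noise": vars(noise),
    }
    (out_dir / "params.json").write_text(json.dumps(params, indent=2))
    return manifest
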