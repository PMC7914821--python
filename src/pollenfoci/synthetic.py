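"""Synthetic two-fluorophore + DAPI pollen z-stacks with known ground truth.

The generator renders a roughly ellipsoidal mature pollen grain whose
vegetative-cell cytoplasm carries a diffuse fluorescent component plus bright
cytoplasmic foci (an mRNP-granule-like clustered point process, optionally
enriched near the male germ unit), a DAPI channel with one large vegetative
nucleus and two small sperm nuclei, and a second fluorophore channel sharing
a controllable fraction of foci with the first.  Gaussian PSF blur, Poisson
shot noise, Gaussian read noise and an additive background offset complete
the imaging model.

The central design constraint is that clustering redistributes rather than
adds signal: each fluorophore channel is rendered as

    B + blur( diffuse * (1 - f) * S  +  foci * f * S ) + noise

where ``S`` is the total expected in-cytoplasm signal, so the expected total
is invariant to the clustered-signal fraction ``f``.  The coefficient of
variation of the rendered cytoplasm therefore responds to *where* the signal
sits, exactly the contrast the CV statistic is meant to detect.

Every random draw is recorded in a :class:`GroundTruth` so downstream masking,
CV and colocalization stages can be tested against construction.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

from .image_io import ZStack

__all__ = [
    "NucleusSpec",
    "ChannelSpec",
    "SyntheticSpec",
    "GroundTruth",
    "spec_from_dict",
    "generate_pollen_stack",
    "generate_condition_series",
    "generate_ct_table",
]


@dataclass(frozen=True)
class NucleusSpec:
    """A spherical nucleus: centre in voxel coordinates (z, y, x), radius in µm."""

    center: tuple[float, float, float]
    radius_um: float
    peak: float


@dataclass(frozen=True)
class ChannelSpec:
    """Parameters of one fluorophore channel.

    ``amplitude`` is the expected diffuse photon count per cytoplasm voxel at
    f = 0 (so total expected signal S = amplitude x cytoplasm voxel count);
    ``clustered_fraction`` (f) moves that fixed total into foci;
    ``foci_rate`` is the Poisson mean of the focus count; ``mgu_fraction``
    (q) is the fraction of foci placed within ``mgu_distance_um`` of a
    nucleus surface, mimicking enrichment around the male germ unit.
    """

    amplitude: float = 60.0
    clustered_fraction: float = 0.1
    foci_rate: float = 80.0
    focus_radius_um: float = 0.35
    mgu_fraction: float = 0.5


# default geometry: 16 optical sections of 256x256 at (1.0, 0.2, 0.2) um,
# a ~36 um grain, one 3.5 um vegetative nucleus + two 1.5 um sperm nuclei
_DEFAULT_VN = NucleusSpec((7.0, 105.0, 128.0), 3.5, 3000.0)
_DEFAULT_SC = (
    NucleusSpec((8.5, 92.0, 142.0), 1.5, 4000.0),
    NucleusSpec((6.5, 88.0, 114.0), 1.5, 4000.0),
)


@dataclass(frozen=True)
class SyntheticSpec:
    """Full parameterisation of one simulated stack (identical spec + seed
    gives bit-identical output)."""

    seed: int = 0
    shape: tuple[int, int, int] = (16, 256, 256)
    voxel_size: tuple[float, float, float] = (1.0, 0.2, 0.2)
    pollen_semiaxes: tuple[float, float, float] = (6.0, 90.0, 90.0)
    pollen_center: tuple[float, float, float] | None = None
    vn: NucleusSpec = _DEFAULT_VN
    sc: tuple[NucleusSpec, NucleusSpec] = _DEFAULT_SC
    channels: Mapping[str, ChannelSpec] = field(
        default_factory=lambda: {"GFP": ChannelSpec(), "RFP": ChannelSpec()}
    )
    coloc_rho: float = 0.5
    mgu_distance_um: float | None = None  # default: 3 focus radii
    psf_sigma: tuple[float, float, float] = (0.5, 1.3, 1.3)
    background: float = 20.0
    gain: float = 1.0  # shot-noise gain; np.inf disables shot noise
    read_noise_sd: float = 3.0
    bit_depth: int = 16
    dapi_name: str = "DAPI"
    sample_id: str = ""
    condition: str = ""
    replicate: int = 0

    def __post_init__(self) -> None:
        for name, ch in self.channels.items():
            if not 0.0 <= ch.clustered_fraction <= 1.0:
                raise ValueError(f"channel {name!r}: clustered_fraction outside [0, 1]")
            if not 0.0 <= ch.mgu_fraction <= 1.0:
                raise ValueError(f"channel {name!r}: mgu_fraction outside [0, 1]")
        if not 0.0 <= self.coloc_rho <= 1.0:
            raise ValueError("coloc_rho outside [0, 1]")
        if self.background < 0 or self.read_noise_sd < 0 or self.gain <= 0:
            raise ValueError("background, read_noise_sd must be >= 0 and gain > 0")
        center = self.pollen_center or tuple(s / 2 for s in self.shape)
        for ax in range(3):
            if center[ax] - self.pollen_semiaxes[ax] < 0 or center[ax] + self.pollen_semiaxes[ax] > self.shape[ax]:
                raise ValueError("pollen ellipsoid extends outside the volume")
        for nuc in (self.vn, *self.sc):
            for ax in range(3):
                r_vox = nuc.radius_um / self.voxel_size[ax]
                if nuc.center[ax] - r_vox < 0 or nuc.center[ax] + r_vox > self.shape[ax]:
                    raise ValueError("nucleus extends outside the volume")

    @property
    def mgu_distance(self) -> float:
        if self.mgu_distance_um is not None:
            return self.mgu_distance_um
        r = max(ch.focus_radius_um for ch in self.channels.values())
        return 3.0 * r


def spec_from_dict(d: Mapping) -> SyntheticSpec:
    """Build a :class:`SyntheticSpec` from a plain (e.g. YAML-loaded) mapping.

    Nested nuclei are given as ``{center: [z,y,x], radius_um: r, peak: p}``,
    channels as ``{name: {amplitude: ..., ...}}``; tuple-valued fields accept
    lists.
    """
    d = dict(d)

    def _nuc(v):
        if isinstance(v, NucleusSpec):
            return v
        return NucleusSpec(tuple(v["center"]), float(v["radius_um"]), float(v.get("peak", 3000.0)))

    if "vn" in d:
        d["vn"] = _nuc(d["vn"])
    if "sc" in d:
        d["sc"] = tuple(_nuc(v) for v in d["sc"])
    if "channels" in d:
        d["channels"] = {
            name: ch if isinstance(ch, ChannelSpec) else ChannelSpec(**ch)
            for name, ch in d["channels"].items()
        }
    for key in ("shape", "voxel_size", "pollen_semiaxes", "pollen_center", "psf_sigma"):
        if d.get(key) is not None:
            d[key] = tuple(d[key])
    return SyntheticSpec(**d)


@dataclass
class GroundTruth:
    """Everything the generator drew, for oracle-style downstream tests."""

    foci_centers: dict[str, np.ndarray]  # (n, 3) voxel coords per channel
    shared_centers: np.ndarray  # (n_shared, 3)
    n_foci: dict[str, int]
    n_shared: int
    clustered_fraction: dict[str, float]
    shared_fraction: float  # n_shared / focus count (rho within rounding)
    nucleus_mask: np.ndarray  # (z, y, x) bool, pre-blur solid nuclei
    pollen_mask: np.ndarray  # (z, y, x) bool ellipsoid
    section_has_nucleus: np.ndarray  # bool per section (area-fraction rule)
    section_has_cytoplasm: np.ndarray  # bool per section
    background: float


# ---------------------------------------------------------------------------
# geometry fields, cached because a condition series reuses one geometry

_geometry_cache: dict[tuple, dict] = {}


def _geometry_key(spec: SyntheticSpec) -> tuple:
    return (
        spec.shape,
        spec.voxel_size,
        spec.pollen_semiaxes,
        spec.pollen_center,
        spec.vn,
        spec.sc,
        spec.psf_sigma,
        spec.mgu_distance,
    )


def _build_geometry(spec: SyntheticSpec) -> dict:
    key = _geometry_key(spec)
    cached = _geometry_cache.get(key)
    if cached is not None:
        return cached

    nz, ny, nx = spec.shape
    center = spec.pollen_center or (nz / 2, ny / 2, nx / 2)
    zz, yy, xx = np.ogrid[:nz, :ny, :nx]
    az, ay, ax = spec.pollen_semiaxes
    rho2 = (
        ((zz - center[0]) / az) ** 2
        + ((yy - center[1]) / ay) ** 2
        + ((xx - center[2]) / ax) ** 2
    )
    pollen = rho2 <= 1.0

    vz, vy, vx = spec.voxel_size
    nucleus = np.zeros(spec.shape, dtype=bool)
    dapi_field = np.zeros(spec.shape, dtype=np.float32)
    dist_um = np.full(spec.shape, np.inf, dtype=np.float32)
    for nuc in (spec.vn, *spec.sc):
        d = np.sqrt(
            ((zz - nuc.center[0]) * vz) ** 2
            + ((yy - nuc.center[1]) * vy) ** 2
            + ((xx - nuc.center[2]) * vx) ** 2
        ).astype(np.float32)
        inside = d <= nuc.radius_um
        nucleus |= inside
        dapi_field[inside] = np.maximum(dapi_field[inside], nuc.peak)
        np.minimum(dist_um, d - nuc.radius_um, out=dist_um)

    cytoplasm = pollen & ~nucleus
    near_mgu = cytoplasm & (dist_um <= spec.mgu_distance)

    dapi_blur = ndimage.gaussian_filter(dapi_field, spec.psf_sigma)
    cyto_blur = ndimage.gaussian_filter(cytoplasm.astype(np.float32), spec.psf_sigma)

    # per-section geometry flags for GroundTruth
    max_area = max(int(pollen[z].sum()) for z in range(nz))
    cyto_area = np.array([int(cytoplasm[z].sum()) for z in range(nz)])
    nuc_area = np.array([int(nucleus[z].sum()) for z in range(nz)])
    pol_area = np.array([int(pollen[z].sum()) for z in range(nz)])
    has_cyto = cyto_area >= max(1, int(0.01 * max_area))
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(pol_area > 0, nuc_area / np.maximum(pol_area, 1), 0.0)
    has_nucleus = frac > 0.01

    geo = {
        "pollen": pollen,
        "nucleus": nucleus,
        "cytoplasm": cytoplasm,
        "cyto_idx": np.flatnonzero(cytoplasm.ravel()),
        "mgu_idx": np.flatnonzero(near_mgu.ravel()),
        "dapi_blur": dapi_blur,
        "cyto_blur": cyto_blur,
        "n_cyto": int(cytoplasm.sum()),
        "has_cyto": has_cyto,
        "has_nucleus": has_nucleus,
    }
    _geometry_cache[key] = geo
    return geo


def _sample_centers(
    rng: np.random.Generator, n: int, q: float, geo: dict, shape: tuple[int, int, int]
) -> np.ndarray:
    """Sample n focus centres: fraction q from the near-MGU shell, rest uniform
    in the cytoplasm."""
    if n == 0:
        return np.empty((0, 3), dtype=np.int64)
    use_mgu = rng.random(n) < q
    if geo["mgu_idx"].size == 0:
        use_mgu[:] = False
    flat = np.where(
        use_mgu,
        rng.choice(geo["mgu_idx"], size=n) if geo["mgu_idx"].size else 0,
        rng.choice(geo["cyto_idx"], size=n),
    )
    return np.stack(np.unravel_index(flat, shape), axis=1)


def _apply_noise(
    rng: np.random.Generator, signal: np.ndarray, spec: SyntheticSpec
) -> np.ndarray:
    out = np.array(signal, dtype=np.float32, copy=True)
    if np.isfinite(spec.gain):
        lit = out > 0  # Poisson(0) is 0: sample only where there is signal
        out[lit] = rng.poisson(spec.gain * out[lit]).astype(np.float32) / spec.gain
    out += spec.background
    if spec.read_noise_sd > 0:
        out += rng.standard_normal(signal.shape, dtype=np.float32) * spec.read_noise_sd
    vmax = float(2**spec.bit_depth - 1)
    np.rint(out, out=out)
    np.clip(out, 0, vmax, out=out)
    return out.astype(np.uint16)


def generate_pollen_stack(spec: SyntheticSpec) -> tuple[ZStack, GroundTruth]:
    """Render one synthetic pollen stack and its ground truth.

    Shared foci (the colocalizing component) are placed first with identical
    centres in both fluorophore channels; each channel then receives its
    channel-specific foci.  The shared count is ``round(rho * n)`` for a
    single Poisson focus-count draw ``n``, so the realised shared fraction
    equals rho within rounding.
    """
    geo = _build_geometry(spec)
    rng = np.random.default_rng(spec.seed)
    names = list(spec.channels)
    if len(names) != 2:
        raise ValueError("exactly two fluorophore channels are required")

    # focus counts: channels with equal rates share one Poisson draw, so
    # rho = 1 really means every focus is shared; with unequal rates the
    # shared component is capped by the smaller count
    rates = [spec.channels[c].foci_rate for c in names]
    if rates[0] == rates[1]:
        n_common = int(rng.poisson(rates[0]))
        n_by = {c: n_common for c in names}
    else:
        n_by = {c: int(rng.poisson(spec.channels[c].foci_rate)) for c in names}
    n_shared = int(round(spec.coloc_rho * min(n_by.values())))
    q_shared = max(spec.channels[c].mgu_fraction for c in names)
    shared = _sample_centers(rng, n_shared, q_shared, geo, spec.shape)

    centers: dict[str, np.ndarray] = {}
    for c in names:
        extra = _sample_centers(
            rng, n_by[c] - n_shared, spec.channels[c].mgu_fraction, geo, spec.shape
        )
        centers[c] = np.concatenate([shared, extra], axis=0)

    channels: dict[str, np.ndarray] = {}
    channels[spec.dapi_name] = _apply_noise(rng, geo["dapi_blur"], spec)

    vz, vy, vx = spec.voxel_size
    for c in names:
        ch = spec.channels[c]
        f = ch.clustered_fraction
        total = ch.amplitude * geo["n_cyto"]  # S
        n = n_by[c]
        diffuse_amp = ch.amplitude * (1.0 - f) if n > 0 else ch.amplitude
        signal = diffuse_amp * geo["cyto_blur"]
        if n > 0 and f > 0:
            foci_img = np.zeros(spec.shape, dtype=np.float32)
            w = f * total / n
            np.add.at(foci_img, tuple(centers[c].T), np.float32(w))
            sigma = tuple(
                float(np.hypot(ch.focus_radius_um / v, p))
                for v, p in zip((vz, vy, vx), spec.psf_sigma)
            )
            signal = signal + ndimage.gaussian_filter(foci_img, sigma)
        channels[c] = _apply_noise(rng, signal, spec)

    stack = ZStack(
        channels=channels,
        voxel_size=spec.voxel_size,
        bit_depth=spec.bit_depth,
        sample_id=spec.sample_id or f"sim_{spec.seed}",
        condition=spec.condition,
        replicate=spec.replicate,
    )
    truth = GroundTruth(
        foci_centers=centers,
        shared_centers=shared,
        n_foci=n_by,
        n_shared=n_shared,
        clustered_fraction={c: spec.channels[c].clustered_fraction for c in names},
        shared_fraction=n_shared / min(n_by.values()) if min(n_by.values()) else 0.0,
        nucleus_mask=geo["nucleus"],
        pollen_mask=geo["pollen"],
        section_has_nucleus=geo["has_nucleus"].copy(),
        section_has_cytoplasm=geo["has_cyto"].copy(),
        background=spec.background,
    )
    return stack, truth


def child_seeds(master_seed: int, n: int) -> list[int]:
    """Deterministic, distinct per-stack seeds derived from a master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def generate_condition_series(
    base_spec: SyntheticSpec,
    f_by_condition: Mapping[str, float] | None = None,
    rho_by_condition: Mapping[str, float] | None = None,
    n_replicates: int = 25,
    seed: int = 0,
) -> list[tuple[ZStack, GroundTruth]]:
    """Generate a labelled replicate series across experimental conditions.

    Exactly one of ``f_by_condition`` (clustered-signal fraction per
    condition, the clustering design) or ``rho_by_condition`` (shared-foci
    fraction per condition, the colocalization design) must be given.
    Per-replicate seeds are derived deterministically from ``seed``.
    """
    if (f_by_condition is None) == (rho_by_condition is None):
        raise ValueError("give exactly one of f_by_condition / rho_by_condition")
    mapping = f_by_condition if f_by_condition is not None else rho_by_condition
    conditions = list(mapping)
    if len(conditions) < 2:
        raise ValueError("need at least two conditions")
    if len(set(conditions)) != len(conditions):
        raise ValueError("duplicate condition labels")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")

    seeds = child_seeds(seed, len(conditions) * n_replicates)
    out: list[tuple[ZStack, GroundTruth]] = []
    i = 0
    for cond in conditions:
        for rep in range(1, n_replicates + 1):
            spec = base_spec
            if f_by_condition is not None:
                new_channels = {
                    name: replace(ch, clustered_fraction=float(mapping[cond]))
                    for name, ch in base_spec.channels.items()
                }
                spec = replace(spec, channels=new_channels)
            else:
                spec = replace(spec, coloc_rho=float(mapping[cond]))
            spec = replace(
                spec,
                seed=seeds[i],
                condition=cond,
                replicate=rep,
                sample_id=f"{cond}_r{rep:02d}",
            )
            out.append(generate_pollen_stack(spec))
            i += 1
    return out


# ---------------------------------------------------------------------------
# qPCR Ct-table generator


def generate_ct_table(
    genes: Sequence[str],
    timepoints: Sequence[str],
    fold_changes: Mapping[tuple[str, str], float],
    n_bio: int = 4,
    n_tech: int = 2,
    noise_sd: float = 0.1,
    tech_sd: float | None = None,
    sample_offset_sd: float = 0.0,
    seed: int = 0,
    reference_genes: Sequence[str] = ("GAPC1", "EIF1a4"),
    baseline_ct: Mapping[str, float] | None = None,
):
    """Simulate a long-format Ct table with programmed fold changes.

    ``fold_changes[(gene, timepoint)]`` is the treated/control expression
    ratio; reference genes are forced to fold 1 everywhere.  Per the usual
    qPCR error model, Ct = baseline - log2(fold) + biological noise (one draw
    per gene per biological replicate, sd ``noise_sd`` cycles) + technical
    noise (one draw per well, sd ``tech_sd``, default ``noise_sd / 2``) + an
    optional per-sample global offset emulating loading differences.

    Returns ``(table, true_folds)`` where ``true_folds`` maps
    (gene, timepoint) to the programmed ratio.
    """
    import pandas as pd

    genes = list(genes)
    for ref in reference_genes:
        if ref not in genes:
            genes.append(ref)
    if tech_sd is None:
        tech_sd = noise_sd / 2.0
    rng = np.random.default_rng(seed)
    base = dict(baseline_ct or {})
    for g in genes:
        base.setdefault(g, 24.0 if g not in reference_genes else 19.0)

    true_folds: dict[tuple[str, str], float] = {}
    rows = []
    for tp in timepoints:
        for treatment in ("control", "treated"):
            for b in range(1, n_bio + 1):
                sample = f"{tp}_{treatment}_b{b}"
                offset = rng.normal(0.0, sample_offset_sd) if sample_offset_sd > 0 else 0.0
                for g in genes:
                    fold = 1.0
                    if treatment == "treated" and g not in reference_genes:
                        fold = float(fold_changes.get((g, tp), 1.0))
                        if fold <= 0:
                            raise ValueError(f"non-positive fold change for {(g, tp)}")
                    if g not in reference_genes:
                        true_folds[(g, tp)] = float(fold_changes.get((g, tp), 1.0))
                    ct0 = base[g] - np.log2(fold) + offset
                    bio = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
                    for t in range(1, n_tech + 1):
                        tech = rng.normal(0.0, tech_sd) if tech_sd > 0 else 0.0
                        rows.append(
                            {
                                "sample_id": sample,
                                "gene": g,
                                "treatment": treatment,
                                "timepoint": tp,
                                "bio_rep": b,
                                "tech_rep": t,
                                "ct": ct0 + bio + tech,
                            }
                        )
    return pd.DataFrame(rows), true_folds
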