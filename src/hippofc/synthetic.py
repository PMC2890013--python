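"""Synthetic resting-state BOLD cohorts with planted hippocampal networks.

No scans accompany the study this package reproduces, so every imaging stage
is exercised on simulated data with known ground truth. The generator plants,
per hemisphere, a band-limited (0.01-0.08 Hz) latent signal shared by an
ipsilateral "mesial temporal" network of voxels around each hippocampus ROI.
Each coupled voxel's series is

    rho * latent + sqrt(1 - rho**2) * idiosyncratic + drift + white noise

where latent and idiosyncratic components are unit-variance band-limited
Gaussian processes (white noise passed through the same rectangular band-pass
operator used in preprocessing, so the planted structure survives filtering),
``rho`` is the hemisphere's coupling, drift is a random cubic polynomial, and
white noise is broadband. The two hemisphere latents are correlated at
``rho_lr``, emulating inter-hippocampal connectivity. Non-network brain
voxels receive drift + noise only.

Group parameter defaults plant the hierarchy seen in the condition being
modelled - controls couple most strongly, right-MTLE less, left-MTLE least,
in BOTH hemispheres - so downstream group contrasts have a known ordering.

All randomness flows from one integer seed through per-(group, subject,
run) ``numpy`` seed sequences, making every cohort bit-reproducible.
"""

from __future__ import annotations

import hashlib
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .images import ROIMask, VolumeSeries
from .preprocessing import band_dof, bandpass_array
from .volumetry import compute_qai

__all__ = [
    "ToyAtlasSpec",
    "ToyAtlas",
    "GroupSimSpec",
    "make_toy_atlas",
    "simulate_subject",
    "simulate_cohort",
    "simulate_volumetry",
    "band_limited_noise",
    "expected_network_correlation",
    "default_group_specs",
    "TABLE1_GROUP_PARAMS",
]

# Label codes of the toy atlas volume.
LABEL_BACKGROUND = 0
LABEL_LEFT_HIPP = 1
LABEL_RIGHT_HIPP = 2
LABEL_LEFT_NETWORK = 3
LABEL_RIGHT_NETWORK = 4
LABEL_OTHER_BRAIN = 5

#: Baseline intensity added to all brain voxels (arbitrary BOLD units).
BASELINE = 100.0


@dataclass
class ToyAtlasSpec:
    """Geometry of the desk-scale toy atlas.

    The default 32x32x16 grid of 2 mm voxels holds two mirrored spherical
    "hippocampus" ROIs and, around each, a larger sphere of ipsilateral
    network voxels, all inside an ellipsoidal brain mask. 2 mm voxels make
    125 voxels exactly 1 cm^3, matching the cluster-extent convention.
    """

    grid_shape: tuple[int, int, int] = (32, 32, 16)
    voxel_size_mm: float = 2.0
    roi_centers: tuple[tuple[int, int, int], tuple[int, int, int]] = ((9, 16, 8), (22, 16, 8))
    roi_radius_vox: int = 2
    network_extent_vox: int = 5

    def validate(self) -> list[str]:
        errors = []
        if len(self.grid_shape) != 3 or any(s <= 0 for s in self.grid_shape):
            errors.append("atlas: grid_shape must be 3 positive integers")
        if not self.voxel_size_mm > 0:
            errors.append("atlas: voxel_size_mm must be positive")
        if self.roi_radius_vox <= 0:
            errors.append("atlas: roi_radius_vox must be positive")
        if self.network_extent_vox < self.roi_radius_vox:
            errors.append("atlas: network_extent_vox must be >= roi_radius_vox")
        (lc, rc) = self.roi_centers
        if np.linalg.norm(np.subtract(lc, rc)) <= 2 * self.roi_radius_vox:
            errors.append("atlas: left and right ROI spheres overlap")
        return errors

    @property
    def affine(self) -> np.ndarray:
        """Grid-to-world affine; x = 0 on the midsagittal plane, all axes centred."""
        v = self.voxel_size_mm
        aff = np.diag([v, v, v, 1.0])
        aff[:3, 3] = -v * (np.array(self.grid_shape) - 1) / 2.0
        return aff


@dataclass
class ToyAtlas:
    """A realized toy atlas: label volume, brain mask, and the two seed ROIs."""

    spec: ToyAtlasSpec
    labels: np.ndarray
    brain: ROIMask
    left_roi: ROIMask
    right_roi: ROIMask

    @property
    def affine(self) -> np.ndarray:
        return self.spec.affine

    @property
    def data(self) -> np.ndarray:  # grid-compatibility shim for check_same_grid
        return self.labels

    def roi(self, side: str) -> ROIMask:
        if side == "left":
            return self.left_roi
        if side == "right":
            return self.right_roi
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")

    def network_mask(self, side: str, include_roi: bool = False) -> np.ndarray:
        """Boolean mask of the planted ipsilateral network voxels."""
        net = LABEL_LEFT_NETWORK if side == "left" else LABEL_RIGHT_NETWORK
        roi = LABEL_LEFT_HIPP if side == "left" else LABEL_RIGHT_HIPP
        mask = self.labels == net
        if include_roi:
            mask |= self.labels == roi
        return mask


def _sphere(grid_shape, center, radius) -> np.ndarray:
    idx = np.indices(grid_shape)
    d2 = sum((idx[a] - center[a]) ** 2 for a in range(3))
    return d2 <= radius**2


def make_toy_atlas(spec: ToyAtlasSpec | None = None) -> ToyAtlas:
    """Build the deterministic toy atlas from its geometric spec.

    Label codes: 0 background, 1 left hippocampus, 2 right hippocampus,
    3 left network, 4 right network, 5 other brain. Network spheres are
    clipped to the brain mask; the hippocampus ROIs must lie strictly inside
    it.
    """
    spec = spec or ToyAtlasSpec()
    errors = spec.validate()
    if errors:
        raise ValueError("; ".join(errors))
    shape = tuple(spec.grid_shape)
    center = (np.array(shape) - 1) / 2.0
    semi = 0.47 * np.array(shape)
    idx = np.indices(shape)
    brain = sum(((idx[a] - center[a]) / semi[a]) ** 2 for a in range(3)) <= 1.0

    left_roi = _sphere(shape, spec.roi_centers[0], spec.roi_radius_vox)
    right_roi = _sphere(shape, spec.roi_centers[1], spec.roi_radius_vox)
    if np.any(left_roi & right_roi):
        raise ValueError("atlas: left and right ROI spheres overlap")
    if np.any(left_roi & ~brain) or np.any(right_roi & ~brain):
        raise ValueError("atlas: ROI voxels fall outside the brain mask")

    left_net = _sphere(shape, spec.roi_centers[0], spec.network_extent_vox) & brain
    right_net = _sphere(shape, spec.roi_centers[1], spec.network_extent_vox) & brain

    labels = np.zeros(shape, dtype=np.int8)
    labels[brain] = LABEL_OTHER_BRAIN
    labels[left_net] = LABEL_LEFT_NETWORK
    labels[right_net] = LABEL_RIGHT_NETWORK
    labels[left_roi] = LABEL_LEFT_HIPP
    labels[right_roi] = LABEL_RIGHT_HIPP

    aff = spec.affine
    return ToyAtlas(
        spec=spec,
        labels=labels,
        brain=ROIMask(brain, aff, "brain"),
        left_roi=ROIMask(left_roi, aff, "left_hippocampus"),
        right_roi=ROIMask(right_roi, aff, "right_hippocampus"),
    )


@dataclass
class GroupSimSpec:
    """Simulation parameters for one cohort group.

    ``rho_ipsi_left``/``rho_ipsi_right`` couple each hemisphere's network
    voxels to that hemisphere's latent signal; ``rho_lr`` correlates the two
    latents. ``noise_sd`` is the broadband white-noise sd relative to the
    unit-variance planted signal; ``drift_amp`` scales the random cubic
    polynomial drift that the band-pass must remove.
    """

    group_label: str = "control"
    n_subjects: int = 9
    runs_per_subject: int = 2
    volumes_per_run: int = 185
    tr_s: float = 2.0
    rho_ipsi_left: float = 0.70
    rho_ipsi_right: float = 0.70
    rho_lr: float = 0.40
    noise_sd: float = 1.0
    drift_amp: float = 1.0
    rng_seed: int = 0

    def validate(self, n_discard: int = 5) -> list[str]:
        errors = []
        if self.n_subjects <= 0:
            errors.append("simulation: n_subjects must be positive")
        if self.runs_per_subject <= 0:
            errors.append("simulation: runs_per_subject must be positive")
        if self.volumes_per_run <= n_discard:
            errors.append(
                f"simulation: volumes_per_run={self.volumes_per_run} must exceed "
                f"the {n_discard} discarded initial volumes"
            )
        if not self.tr_s > 0:
            errors.append("simulation: tr_s must be positive")
        for name in ("rho_ipsi_left", "rho_ipsi_right"):
            if not 0 <= getattr(self, name) <= 1:
                errors.append(f"simulation: {name} must be in [0, 1]")
        if not -1 <= self.rho_lr <= 1:
            errors.append("simulation: rho_lr must be in [-1, 1] (latent covariance PSD)")
        if not self.noise_sd > 0:
            errors.append("simulation: noise_sd must be positive")
        if self.drift_amp < 0:
            errors.append("simulation: drift_amp must be nonnegative")
        return errors


def default_group_specs(
    rng_seed: int = 0,
    n_subjects: int = 9,
    runs_per_subject: int = 2,
    volumes_per_run: int = 185,
) -> list[GroupSimSpec]:
    """The three default cohort groups with the planted coupling hierarchy.

    Controls couple at 0.70 bilaterally; right-MTLE loses coupling mostly in
    the right (sclerotic) hemisphere; left-MTLE loses most coupling overall,
    in both hemispheres - the qualitative pattern the group contrasts are
    expected to recover.
    """
    common = dict(
        n_subjects=n_subjects,
        runs_per_subject=runs_per_subject,
        volumes_per_run=volumes_per_run,
        rng_seed=rng_seed,
    )
    return [
        GroupSimSpec(group_label="control", rho_ipsi_left=0.70, rho_ipsi_right=0.70,
                     rho_lr=0.40, **common),
        GroupSimSpec(group_label="right_mtle", rho_ipsi_left=0.60, rho_ipsi_right=0.55,
                     rho_lr=0.15, **common),
        GroupSimSpec(group_label="left_mtle", rho_ipsi_left=0.40, rho_ipsi_right=0.45,
                     rho_lr=0.10, **common),
    ]


def band_limited_noise(
    rng: np.random.Generator,
    n_series: int,
    n_timepoints: int,
    tr_s: float,
    f_lo: float = 0.01,
    f_hi: float = 0.08,
) -> np.ndarray:
    """Unit-variance Gaussian series with all power inside (f_lo, f_hi).

    White noise is pushed through the rectangular band-pass projector and
    standardized per series, so the realized sample variance is exactly 1.
    """
    white = rng.standard_normal((n_series, n_timepoints))
    filtered = bandpass_array(white, tr_s, f_lo, f_hi, axis=-1)
    sd = filtered.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return filtered / sd


def _run_rng(
    rng_seed: int, subject_index: int, run_index: int, group_label: str = ""
) -> np.random.Generator:
    """Counter-based stream: one independent generator per (group, subject, run).

    The group label enters the key so that cohorts sharing one master seed
    still draw independent noise across groups - without it, subject i of
    every group would receive identical latent realizations and the
    between-group tests would compare correlated samples.
    """
    group_key = zlib.crc32(group_label.encode())
    return np.random.default_rng(
        np.random.SeedSequence(
            [int(rng_seed), int(group_key), int(subject_index), int(run_index)]
        )
    )


def simulate_subject(
    atlas: ToyAtlas,
    group_spec: GroupSimSpec,
    subject_index: int,
    f_lo: float = 0.01,
    f_hi: float = 0.08,
) -> list[VolumeSeries]:
    """Simulate one subject's resting-state runs on the toy atlas grid.

    Returns one ``VolumeSeries`` per run, reproducible from
    (rng_seed, subject_index, run index) alone.
    """
    errors = group_spec.validate()
    if errors:
        raise ValueError("; ".join(errors))
    shape = tuple(atlas.spec.grid_shape)
    if atlas.labels.shape != shape:
        raise ValueError("atlas labels inconsistent with its own spec")
    T = group_spec.volumes_per_run
    tr = group_spec.tr_s

    brain = atlas.brain.data
    brain_idx = np.nonzero(brain)
    n_brain = len(brain_idx[0])
    labels_flat = atlas.labels[brain_idx]
    left_coupled = (labels_flat == LABEL_LEFT_HIPP) | (labels_flat == LABEL_LEFT_NETWORK)
    right_coupled = (labels_flat == LABEL_RIGHT_HIPP) | (labels_flat == LABEL_RIGHT_NETWORK)

    # normalized time in [-1, 1] and a cubic polynomial drift basis
    tau = np.linspace(-1.0, 1.0, T)
    drift_basis = np.stack([tau, 0.5 * (3 * tau**2 - 1), 0.5 * (5 * tau**3 - 3 * tau)])

    runs = []
    for run_index in range(group_spec.runs_per_subject):
        rng = _run_rng(group_spec.rng_seed, subject_index, run_index,
                       group_spec.group_label)

        # hemisphere latents, correlated at rho_lr before filtering
        w = rng.standard_normal((2, T))
        w[1] = group_spec.rho_lr * w[0] + np.sqrt(1 - group_spec.rho_lr**2) * w[1]
        latents = bandpass_array(w, tr, f_lo, f_hi, axis=-1)
        latents /= latents.std(axis=-1, keepdims=True)

        signal = np.zeros((n_brain, T))
        for coupled, rho, latent in (
            (left_coupled, group_spec.rho_ipsi_left, latents[0]),
            (right_coupled, group_spec.rho_ipsi_right, latents[1]),
        ):
            n_vox = int(coupled.sum())
            if n_vox == 0:
                continue
            idio = band_limited_noise(rng, n_vox, T, tr, f_lo, f_hi)
            signal[coupled] = rho * latent + np.sqrt(1 - rho**2) * idio

        drift = group_spec.drift_amp * (
            rng.standard_normal((n_brain, 3)) @ drift_basis
        )
        noise = group_spec.noise_sd * rng.standard_normal((n_brain, T))

        data = np.zeros(shape + (T,), dtype=np.float32)
        data[brain_idx] = (BASELINE + signal + drift + noise).astype(np.float32)
        runs.append(VolumeSeries(data, atlas.affine, tr))
    return runs


def simulate_cohort(
    atlas: ToyAtlas,
    specs: list[GroupSimSpec],
    out_dir,
) -> pd.DataFrame:
    """Simulate every group and write runs as NIfTI-1 plus a TSV manifest.

    The manifest (``manifest.tsv``) has one row per run with columns
    subject_id, group, subject_index, run, path; paths are relative to
    ``out_dir``. Re-running with identical specs reproduces identical files.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out_dir}: {exc}") from exc
    rows = []
    for spec in specs:
        for subject_index in range(spec.n_subjects):
            subject_id = f"{spec.group_label}_{subject_index + 1:02d}"
            runs = simulate_subject(atlas, spec, subject_index)
            for run_index, run in enumerate(runs):
                rel = f"{subject_id}_run{run_index + 1:02d}.nii.gz"
                run.save(out_dir / rel)
                rows.append(
                    dict(subject_id=subject_id, group=spec.group_label,
                         subject_index=subject_index, run=run_index, path=rel)
                )
    manifest = pd.DataFrame(
        rows, columns=["subject_id", "group", "subject_index", "run", "path"]
    )
    manifest.to_csv(out_dir / "manifest.tsv", sep="\t", index=False)
    return manifest


def simulate_noise_subject(
    atlas: ToyAtlas,
    n_runs: int = 2,
    volumes_per_run: int = 185,
    tr_s: float = 2.0,
    noise_sd: float = 1.0,
    rng_seed: int = 0,
    subject_index: int = 0,
) -> list[VolumeSeries]:
    """A pure-noise subject: iid white Gaussian series in every brain voxel.

    No latent signal, no drift, no temporal structure of any kind - the
    null case under which the parametric correlation p-values are exactly
    calibrated. Used for false-positive-rate checks.
    """
    shape = tuple(atlas.spec.grid_shape)
    brain_idx = np.nonzero(atlas.brain.data)
    runs = []
    for run_index in range(n_runs):
        rng = _run_rng(rng_seed, subject_index, run_index)
        data = np.zeros(shape + (volumes_per_run,), dtype=np.float32)
        data[brain_idx] = (
            BASELINE
            + noise_sd * rng.standard_normal((len(brain_idx[0]), volumes_per_run))
        ).astype(np.float32)
        runs.append(VolumeSeries(data, atlas.affine, tr_s))
    return runs


#: Per-group (mean, sd) of left and right hippocampal volume in mm^3, taken
#: from the study cohort's summary statistics; used as simulation defaults.
TABLE1_GROUP_PARAMS = {
    "control": {"vlh": (4895.4, 662.7), "vrh": (4762.2, 381.6)},
    "right_mtle": {"vlh": (4864.6, 992.5), "vrh": (3375.8, 681.1)},
    "left_mtle": {"vlh": (3756.1, 1255.3), "vrh": (4880.7, 853.9)},
}


def simulate_volumetry(
    group_params: dict | None = None,
    n_per_group: int = 9,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Draw a synthetic volumetry table from per-group normal distributions.

    Volumes are drawn from N(mean, sd) truncated at 0 (redrawn if
    nonpositive); the asymmetry index column is recomputed from the drawn
    volumes. ``sd = 0`` collapses every subject onto the group mean.
    """
    group_params = group_params or TABLE1_GROUP_PARAMS
    if n_per_group <= 0:
        raise ValueError("n_per_group must be positive")
    for group, params in group_params.items():
        for key in ("vlh", "vrh"):
            if params[key][1] < 0:
                raise ValueError(f"simulation: sd for {group}/{key} must be nonnegative")
    rng = np.random.default_rng(np.random.SeedSequence([int(rng_seed), 0xB07]))

    def draw(mean, sd):
        if sd == 0:
            return float(mean)
        v = rng.normal(mean, sd)
        while v <= 0:
            v = rng.normal(mean, sd)
        return float(v)

    rows = []
    for group, params in group_params.items():
        for i in range(n_per_group):
            vlh = draw(*params["vlh"])
            vrh = draw(*params["vrh"])
            rows.append(
                dict(subject_id=f"{group}_{i + 1:02d}", group=group,
                     vlh_mm3=vlh, vrh_mm3=vrh, qai=compute_qai(vlh, vrh))
            )
    return pd.DataFrame(rows)


def expected_network_correlation(
    rho: float,
    m_seed_voxels: int,
    noise_sd: float,
    n_timepoints: int,
    tr_s: float = 2.0,
    f_lo: float = 0.01,
    f_hi: float = 0.08,
) -> float:
    """Closed-form seed-to-network-voxel correlation after band-passing.

    From the generator's variance decomposition: the seed (mean over m ROI
    voxels) has variance rho^2 + ((1-rho^2) + nf)/m and a network voxel
    1 + nf, sharing covariance rho^2, where nf = noise_sd^2 * d/T is the
    white-noise variance surviving a band-pass of real dimension d. Drift is
    annihilated by the filter and drops out.
    """
    nf = noise_sd**2 * band_dof(n_timepoints, tr_s, f_lo, f_hi) / n_timepoints
    var_seed = rho**2 + ((1 - rho**2) + nf) / m_seed_voxels
    var_voxel = 1.0 + nf
    return rho**2 / np.sqrt(var_seed * var_voxel)


def file_checksum(path) -> str:
    """SHA-256 of a file, for manifest determinism checks."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
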