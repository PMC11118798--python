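"""Synthetic data generation: paradigms, latent drives, cohorts, surrogates.

Emulates a thermal-stimulation fMRI session: 270-s runs sampled at a
repetition time of 6.75 s (40 volumes), a cue at the 1-min mark, and — in
the Pain condition only — a 30-s block of 10 brief heat contacts starting
at 120 s.  Region time-courses are produced by driving a directed network
model (``sapm.model.forward_model``) with hemodynamically convolved latent
inputs, so every downstream stage has a known ground truth.
"""
from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .network import NetworkModel

__all__ = [
    "PAIN",
    "NO_PAIN",
    "RUNS_PER_CONDITION",
    "Paradigm",
    "StimulusProtocol",
    "GroundTruth",
    "CohortConfig",
    "ParticipantDataset",
    "build_paradigm",
    "hrf",
    "neural_design",
    "bold_from_neural",
    "generate_participant",
    "generate_cohort",
    "normalized_pain_score",
    "phase_randomize",
    "render_nifti",
    "table2_ground_truth",
    "cohort_to_frame",
    "covariates_to_frame",
    "frame_to_timecourses",
]

PAIN = "pain"
NO_PAIN = "no_pain"
Condition = Literal["pain", "no_pain"]

#: runs acquired per condition in one imaging session
RUNS_PER_CONDITION = 5

_RUN_DURATION_S = 270.0
_TR_S = 6.75
_CUE_ONSET_S = 60.0
_STIM_START_S = 120.0
_N_CONTACTS = 10
_CONTACT_SPACING_S = 3.0
_CONTACT_DURATION_S = 1.5


def stage_seed(master: int, stage: str, item: object = None) -> int:
    """Deterministic 32-bit seed as a pure function of (master, stage, item)."""
    token = f"{master}:{stage}:{item}".encode()
    return int.from_bytes(hashlib.sha256(token).digest()[:4], "big")


# -- paradigm --------------------------------------------------------------

@dataclass(frozen=True)
class Paradigm:
    """Volume-sampled timing of one run of a single condition."""

    condition: str
    duration_s: float = _RUN_DURATION_S
    tr_s: float = _TR_S
    n_volumes: int = 40
    cue_onset_s: float = _CUE_ONSET_S
    stim_onsets_s: tuple[float, ...] = ()
    contact_duration_s: float = _CONTACT_DURATION_S

    def __post_init__(self) -> None:
        if abs(self.n_volumes * self.tr_s - self.duration_s) > 1e-9:
            raise ValueError("n_volumes * tr_s must equal duration_s")

    @property
    def volume_times_s(self) -> np.ndarray:
        return np.arange(self.n_volumes) * self.tr_s


@dataclass(frozen=True)
class StimulusProtocol:
    """Calibrated heat temperatures, one per stimulation run."""

    temperatures_C: tuple[float, ...] = (46.0, 50.0, 44.0, 48.0)


def build_paradigm(condition: str) -> Paradigm:
    """Study paradigm: 270 s at TR 6.75 s, cue at 60 s, contacts at 120..147 s."""
    if condition not in (PAIN, NO_PAIN):
        raise ValueError(f"condition must be {PAIN!r} or {NO_PAIN!r}, got {condition!r}")
    onsets: tuple[float, ...] = ()
    if condition == PAIN:
        onsets = tuple(
            _STIM_START_S + i * _CONTACT_SPACING_S for i in range(_N_CONTACTS)
        )
    return Paradigm(condition=condition, stim_onsets_s=onsets)


def condition_volume_count(p: Paradigm, n_runs: int = RUNS_PER_CONDITION) -> int:
    """Volumes available per condition before run-averaging."""
    return n_runs * p.n_volumes


# -- hemodynamics ----------------------------------------------------------

_HRF_GRID = np.linspace(0.0, 40.0, 8001)
_HRF_PEAK = None


def _hrf_raw(t: np.ndarray) -> np.ndarray:
    # canonical double-gamma: positive lobe peaking near 5 s, late undershoot
    return sps.gamma.pdf(t, 6.0) - sps.gamma.pdf(t, 16.0) / 6.0


def hrf(t: float | np.ndarray) -> float | np.ndarray:
    """Canonical double-gamma hemodynamic response, unit peak amplitude."""
    global _HRF_PEAK
    if _HRF_PEAK is None:
        _HRF_PEAK = _hrf_raw(_HRF_GRID).max()
    t = np.asarray(t, dtype=float)
    out = np.where(t >= 0, _hrf_raw(np.clip(t, 0.0, None)) / _HRF_PEAK, 0.0)
    return float(out) if out.ndim == 0 else out


# -- neural designs --------------------------------------------------------

NEURAL_DT_S = 0.25  # divides the TR (6.75 s) exactly
#: order in which neural components map onto declared latent inputs
NEURAL_COMPONENTS = ("stim", "cue", "tonic")


def neural_design(p: Paradigm, dt_s: float = NEURAL_DT_S) -> dict[str, np.ndarray]:
    """Second-resolution neural time-series underlying the latent inputs.

    Components: ``stim`` (boxcars over the heat contacts; identically zero
    in the No-Pain condition), ``cue`` (transient at the cue), and ``tonic``
    (a slow full-run modulation).  Each component is mean-centered.
    """
    t = np.arange(0.0, p.duration_s, dt_s)
    cue = ((t >= p.cue_onset_s) & (t < p.cue_onset_s + 3.0)).astype(float)
    stim = np.zeros_like(t)
    for onset in p.stim_onsets_s:
        stim += ((t >= onset) & (t < onset + p.contact_duration_s)).astype(float)
    tonic = np.cos(2 * np.pi * t / p.duration_s)
    out = {}
    for name, series in (("stim", stim), ("cue", cue), ("tonic", tonic)):
        if np.any(series != 0):
            series = series - series.mean()
        out[name] = series
    return out


def bold_from_neural(
    neural: np.ndarray, tr_s: float, dt_s: float = NEURAL_DT_S
) -> np.ndarray:
    """Convolve a neural series with the HRF and sample at volume times.

    Output is zero-mean / unit-variance (all-zero input stays all-zero).
    """
    neural = np.asarray(neural, dtype=float)
    duration = neural.size * dt_s
    if duration < tr_s:
        raise ValueError("neural series shorter than one TR")
    kernel = hrf(np.arange(0.0, 48.0, dt_s)) * dt_s
    conv = np.convolve(neural, kernel)[: neural.size]
    n_vol = int(np.floor(duration / tr_s + 1e-9))
    idx = np.round(np.arange(n_vol) * tr_s / dt_s).astype(int)
    sampled = conv[idx]
    sampled = sampled - sampled.mean()
    sd = sampled.std()
    if sd > 0:
        sampled = sampled / sd
    return sampled


def paradigm_latents(p: Paradigm, n_latents: int, orthogonalize: bool = True) -> np.ndarray:
    """Volume-sampled latent drives for ``n_latents`` latent inputs.

    Components are assigned in ``NEURAL_COMPONENTS`` order and cycled if
    more latents are declared.  With ``orthogonalize`` the series are
    Gram-Schmidt orthogonalized (then re-standardized), which keeps the
    latent drives mutually uncorrelated at the volume level.
    """
    design = neural_design(p)
    series = []
    for i in range(n_latents):
        comp = NEURAL_COMPONENTS[i % len(NEURAL_COMPONENTS)]
        series.append(bold_from_neural(design[comp], p.tr_s))
    L = np.array(series)
    if orthogonalize:
        for i in range(1, L.shape[0]):
            for j in range(i):
                denom = float(L[j] @ L[j])
                if denom > 0:
                    L[i] = L[i] - (L[i] @ L[j]) / denom * L[j]
            L[i] = L[i] - L[i].mean()
            sd = L[i].std()
            if sd > 0:
                L[i] = L[i] / sd
    return L


# -- ground truth ----------------------------------------------------------

@dataclass
class GroundTruth:
    """Generative connection weights for one group/condition.

    ``db_mean`` maps (source, target) — including (latent, target) links —
    to the population-mean weight; ``db_sd_between`` holds the
    between-participant SD (missing keys default to 0).
    """

    db_mean: dict[tuple[str, str], float]
    db_sd_between: dict[tuple[str, str], float] = field(default_factory=dict)
    latent_gain: dict[tuple[str, str], float] = field(default_factory=dict)

    def mean_for(self, key: tuple[str, str]) -> float:
        return self.db_mean.get(key, 0.0)

    def sd_for(self, key: tuple[str, str]) -> float:
        return self.db_sd_between.get(key, 0.0)


#: group-mean weight and printed uncertainty (interpreted as SEM at n = 15)
#: for the seven connections with reported per-condition values, keyed by
#: ``(group, condition)`` column.
TABLE2_DB: dict[tuple[str, str], dict[tuple[str, str], tuple[float, float]]] = {
    ("FM", PAIN): {
        ("PBN", "Thalamus"): (0.166, 0.040),
        ("LC", "Hypothalamus"): (0.319, 0.107),
        ("PBN", "Hypothalamus"): (0.165, 0.063),
        ("Hypothalamus", "LC"): (0.227, 0.110),
        ("LC", "Thalamus"): (0.286, 0.107),
        ("LC", "DRt"): (-0.074, 0.127),
        ("LC", "PBN"): (0.119, 0.113),
    },
    ("FM", NO_PAIN): {
        ("PBN", "Thalamus"): (0.185, 0.087),
        ("LC", "Hypothalamus"): (0.436, 0.137),
        ("PBN", "Hypothalamus"): (0.254, 0.048),
        ("Hypothalamus", "LC"): (0.311, 0.110),
        ("LC", "Thalamus"): (0.286, 0.108),
        ("LC", "DRt"): (-0.438, 0.103),
        ("LC", "PBN"): (0.324, 0.160),
    },
    ("HC", PAIN): {
        ("PBN", "Thalamus"): (0.282, 0.078),
        ("LC", "Hypothalamus"): (0.376, 0.137),
        ("PBN", "Hypothalamus"): (0.103, 0.050),
        ("Hypothalamus", "LC"): (0.088, 0.161),
        ("LC", "Thalamus"): (0.528, 0.097),
        ("LC", "DRt"): (-0.326, 0.119),
        ("LC", "PBN"): (0.439, 0.123),
    },
    ("HC", NO_PAIN): {
        ("PBN", "Thalamus"): (0.305, 0.078),
        ("LC", "Hypothalamus"): (0.255, 0.150),
        ("PBN", "Hypothalamus"): (0.266, 0.089),
        ("Hypothalamus", "LC"): (0.128, 0.172),
        ("LC", "Thalamus"): (0.379, 0.098),
        ("LC", "PBN"): (0.274, 0.105),
    },
}

#: fixture weights for pathways without reported per-condition values;
#: chosen so every tabulated connection's source/target regressors carry
#: linearly independent signal (see docs in ``table2_ground_truth``).
_BASELINE_DB: dict[tuple[str, str], float] = {
    ("C6RD", "PBN"): 0.20,
    ("C6RD", "NTS"): 0.20,
    ("Hypothalamus", "PAG"): 0.20,
}
_GROUP_DB: dict[str, dict[tuple[str, str], float]] = {
    # reported group means of the covariance analysis (Pain condition),
    # reused for both conditions as generator fixtures
    "FM": {("C6RD", "Thalamus"): -0.113, ("PAG", "NTS"): 0.084},
    "HC": {("C6RD", "Thalamus"): -0.012, ("PAG", "NTS"): 0.120},
}

_COHORT_N = 15  # participants per group in the emulated study


def table2_ground_truth(
    group: str,
    condition: str,
    *,
    n_for_sem: int = _COHORT_N,
    latent_gain: float = 1.0,
    net: NetworkModel | None = None,
) -> GroundTruth:
    """Ground truth from the tabulated per-connection group values.

    The printed ``±`` is interpreted as the SEM of the group mean, so the
    between-participant SD defaults to ``sem * sqrt(n_for_sem)``.  Latent
    links get weight ``latent_gain`` with zero between-participant SD.
    """
    try:
        column = TABLE2_DB[(group, condition)]
    except KeyError as exc:
        raise KeyError(f"no tabulated column for {(group, condition)!r}") from exc
    db_mean: dict[tuple[str, str], float] = {}
    db_sd: dict[tuple[str, str], float] = {}
    for key, (mean, sem) in column.items():
        db_mean[key] = mean
        db_sd[key] = sem * np.sqrt(n_for_sem)
    db_mean.update(_BASELINE_DB)
    db_mean.update(_GROUP_DB.get(group, {}))
    gains: dict[tuple[str, str], float] = {}
    if net is not None:
        for l in net.latents:
            for t in l.targets:
                gains[(l.name, t)] = latent_gain
                db_mean[(l.name, t)] = latent_gain
    return GroundTruth(db_mean=db_mean, db_sd_between=db_sd, latent_gain=gains)


# -- participants & cohorts ------------------------------------------------

@dataclass
class ParticipantDataset:
    """Run-averaged sub-region time-courses and covariates for one participant."""

    participant_id: str
    group: str
    data: dict[str, np.ndarray]  # condition -> (regions, n_subregions, n_volumes)
    regions: list[str]
    signal_subregion: dict[str, int]  # region -> 1-based signal-bearing index
    true_db: dict[str, dict[tuple[str, str], float]] = field(default_factory=dict)
    covariates: dict[str, float] = field(default_factory=dict)

    def region_series(self, condition: str, choice: Mapping[str, int] | None = None) -> np.ndarray:
        """(regions, volumes) matrix picking one sub-region per region.

        ``choice`` maps region -> 1-based sub-region index; defaults to the
        signal-bearing sub-region recorded by the generator.
        """
        cube = self.data[condition]
        if choice is None:
            choice = self.signal_subregion
        rows = [cube[i, choice[r] - 1] for i, r in enumerate(self.regions)]
        return np.array(rows)


class StabilityError(ValueError):
    """Raised when drawn generative weights make the network unstable."""


def _db_matrix(net: NetworkModel, db: Mapping[tuple[str, str], float]) -> np.ndarray:
    regions = net.region_abbrevs
    ix = {a: i for i, a in enumerate(regions)}
    A = np.zeros((len(regions), len(regions)))
    for c in net.connections:
        A[ix[c.target], ix[c.source]] = db.get(c.key, 0.0)
    return A


def _draw_db(
    net: NetworkModel, gt: GroundTruth, rng: np.random.Generator, max_tries: int = 20
) -> dict[tuple[str, str], float]:
    keys = net.connection_keys(include_latent=True)
    for _ in range(max_tries):
        db = {k: rng.normal(gt.mean_for(k), gt.sd_for(k)) for k in keys}
        A = _db_matrix(net, db)
        if np.max(np.abs(np.linalg.eigvals(A))) < 0.95:
            return db
    raise StabilityError(
        "could not draw stable participant weights; reduce db_sd_between"
    )


def generate_participant(
    net: NetworkModel,
    gt: GroundTruth,
    p: Paradigm,
    noise_sd: float = 0.1,
    seed: int = 0,
    *,
    participant_id: str = "sub-000",
    group: str = "NA",
    attenuation: float = 0.3,
    db: Mapping[tuple[str, str], float] | None = None,
    signal_subregion: Mapping[str, int] | None = None,
) -> ParticipantDataset:
    """One participant's run-averaged data for one condition.

    Per-connection weights are drawn once from ``Normal(db_mean,
    db_sd_between)`` (pass ``db`` to pin them), latent drives come from the
    paradigm, region outputs from the network forward model.  In each
    region one randomly chosen sub-region carries the full network signal;
    the others carry the signal attenuated by ``attenuation``.  Gaussian
    noise of SD ``noise_sd`` (interpreted as post-run-averaging noise) is
    added to every sub-region series, which are then mean-centered.
    """
    from .model import forward_model  # local import to avoid a cycle

    rng = np.random.default_rng(seed)
    if db is None:
        db = _draw_db(net, gt, rng)
    else:
        db = dict(db)
        A = _db_matrix(net, db)
        radius = float(np.max(np.abs(np.linalg.eigvals(A))))
        if radius >= 1.0:
            raise StabilityError(f"supplied weights are unstable (radius {radius:.3f})")
    latent_names = [l.name for l in net.latents]
    L = paradigm_latents(p, len(latent_names))
    signals = forward_model(net, db, list(zip(latent_names, L)))

    regions = net.region_abbrevs
    n_sub = max(r.n_subregions for r in net.regions) if net.regions else 0
    n_vol = p.n_volumes
    cube = np.zeros((len(regions), n_sub, n_vol))
    signal_sub: dict[str, int] = {}
    for i, r in enumerate(regions):
        k = net.region(r).n_subregions
        if signal_subregion is not None:
            sig = int(signal_subregion[r])
        else:
            sig = int(rng.integers(0, k)) + 1
        signal_sub[r] = sig
        for j in range(k):
            scale = 1.0 if (j + 1) == sig else attenuation
            series = scale * signals[i]
            if noise_sd > 0:
                series = series + rng.normal(0.0, noise_sd, n_vol)
            cube[i, j] = series - series.mean()
    return ParticipantDataset(
        participant_id=participant_id,
        group=group,
        data={p.condition: cube},
        regions=list(regions),
        signal_subregion=signal_sub,
        true_db={p.condition: dict(db)},
    )


@dataclass
class CohortConfig:
    """Cohort-level generation settings."""

    n_per_group: int = _COHORT_N
    noise_sd: float = 0.1
    seed: int = 0
    rating_mean_sd: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"HC": (24.6, 14.4), "FM": (41.6, 14.2)}
    )
    last_rating_delta: dict[str, float] = field(
        default_factory=lambda: {"HC": 12.2, "FM": 4.5}
    )
    temperatures_C: tuple[float, ...] = StimulusProtocol().temperatures_C
    rating_coupling: tuple[tuple[str, str], float] | None = None

    def validate(self) -> list[str]:
        issues = []
        if self.n_per_group < 2:
            issues.append("n_per_group must be >= 2")
        if self.noise_sd < 0:
            issues.append("noise_sd must be >= 0")
        if self.rating_coupling is not None and not -1 <= self.rating_coupling[1] <= 1:
            issues.append("rating_coupling correlation must be in [-1, 1]")
        return issues


def generate_cohort(
    net: NetworkModel,
    gt_fm: GroundTruth | Mapping[str, GroundTruth],
    gt_hc: GroundTruth | Mapping[str, GroundTruth],
    cfg: CohortConfig,
) -> list[ParticipantDataset]:
    """Generate both conditions for ``n_per_group`` FM and HC participants.

    ``gt_fm`` / ``gt_hc`` may be a single :class:`GroundTruth` (used for
    both conditions) or a mapping ``condition -> GroundTruth``.  With
    ``cfg.rating_coupling = ((src, tgt), rho)`` the first-contact rating is
    drawn with correlation ``rho`` to the participant's Pain-condition
    weight on that connection.
    """
    issues = cfg.validate()
    if issues:
        raise ValueError("; ".join(issues))
    paradigms = {PAIN: build_paradigm(PAIN), NO_PAIN: build_paradigm(NO_PAIN)}
    out: list[ParticipantDataset] = []
    for group, gt_any in (("FM", gt_fm), ("HC", gt_hc)):
        gts: Mapping[str, GroundTruth]
        gts = gt_any if isinstance(gt_any, Mapping) else {PAIN: gt_any, NO_PAIN: gt_any}
        mean, sd = cfg.rating_mean_sd[group]
        delta = cfg.last_rating_delta[group]
        for i in range(cfg.n_per_group):
            pid = f"sub-{group}{i:03d}"
            draw_rng = np.random.default_rng(stage_seed(cfg.seed, "db", pid))
            sub_rng = np.random.default_rng(stage_seed(cfg.seed, "subregion", pid))
            choice = {
                r.abbrev: int(sub_rng.integers(0, r.n_subregions)) + 1
                for r in net.regions
            }
            ds: ParticipantDataset | None = None
            for cond in (PAIN, NO_PAIN):
                gt = gts.get(cond) if hasattr(gts, "get") else None
                if gt is None:
                    gt = next(iter(gts.values()))
                db = _draw_db(net, gt, draw_rng)
                part = generate_participant(
                    net,
                    gt,
                    paradigms[cond],
                    noise_sd=cfg.noise_sd,
                    seed=stage_seed(cfg.seed, f"participant:{cond}", pid),
                    participant_id=pid,
                    group=group,
                    db=db,
                    signal_subregion=choice,
                )
                if ds is None:
                    ds = part
                else:
                    ds.data[cond] = part.data[cond]
                    ds.true_db[cond] = part.true_db[cond]
            assert ds is not None
            rate_rng = np.random.default_rng(stage_seed(cfg.seed, "rating", pid))
            eps = rate_rng.normal()
            if cfg.rating_coupling is not None:
                key, rho = cfg.rating_coupling
                key = tuple(key)  # type: ignore[assignment]
                gt_pain = gts.get(PAIN) or next(iter(gts.values()))
                sd_key = gt_pain.sd_for(key)  # type: ignore[arg-type]
                if sd_key > 0:
                    z = (ds.true_db[PAIN][key] - gt_pain.mean_for(key)) / sd_key  # type: ignore[index,arg-type]
                    eps = rho * z + np.sqrt(max(0.0, 1 - rho**2)) * eps
            first = float(np.clip(mean + sd * eps, 0.0, 100.0))
            last = float(np.clip(first + rate_rng.normal(delta, 5.0), 0.0, 100.0))
            ds.covariates = {
                "first_pain_rating": first,
                "last_pain_rating": last,
                "normalized_pain_score": normalized_pain_score(
                    [first, last], cfg.temperatures_C
                ),
            }
            out.append(ds)
    return out


def normalized_pain_score(
    ratings: Sequence[float], temperatures_C: Sequence[float]
) -> float:
    """Mean pain rating divided by mean stimulus temperature."""
    if len(ratings) == 0 or len(temperatures_C) == 0:
        raise ValueError("ratings and temperatures must be non-empty")
    temps = np.asarray(temperatures_C, dtype=float)
    if np.any(temps <= 0):
        raise ValueError("temperatures must be positive")
    return float(np.mean(ratings) / temps.mean())


# -- surrogates ------------------------------------------------------------

def phase_randomize(series: np.ndarray, seed: int = 0) -> np.ndarray:
    """Phase-randomized surrogate preserving the Fourier amplitude spectrum."""
    x = np.asarray(series, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError("series must have length >= 4")
    rng = np.random.default_rng(seed)
    spec = np.fft.rfft(x)
    out = spec.copy()
    # bins strictly between DC and (for even n) Nyquist get free phases
    hi = n // 2 if n % 2 == 0 else (n + 1) // 2
    phases = rng.uniform(0.0, 2 * np.pi, hi - 1)
    out[1:hi] = np.abs(spec[1:hi]) * np.exp(1j * phases)
    if n % 2 == 0:
        out[hi] = spec[hi] * rng.choice([-1.0, 1.0])
    return np.fft.irfft(out, n=n)


# -- image fixtures --------------------------------------------------------

def render_nifti(
    ds: ParticipantDataset,
    geometry: int,
    condition: str = PAIN,
    voxel_noise_sd: float = 0.0,
    seed: int = 0,
):
    """Render one condition of a dataset as a 4-D NIfTI + integer label map.

    Each region occupies ``geometry`` voxels laid out along x at its own y
    row; sub-regions own contiguous near-equal x chunks and every voxel
    carries its sub-region's series plus optional voxel noise.  Region
    label codes are 1-based region indices.  Returns
    ``(img4d, labelmap_img, code_map)``.
    """
    import nibabel as nib

    cube = ds.data[condition]
    n_regions, n_sub, n_vol = cube.shape
    if geometry < n_sub:
        raise ValueError("geometry must provide at least one voxel per sub-region")
    rng = np.random.default_rng(seed)
    data = np.zeros((geometry, n_regions, 1, n_vol), dtype=np.float64)
    labels = np.zeros((geometry, n_regions, 1), dtype=np.int16)
    chunks = np.array_split(np.arange(geometry), n_sub)
    for i in range(n_regions):
        labels[:, i, 0] = i + 1
        for j, chunk in enumerate(chunks):
            for v in chunk:
                series = cube[i, j]
                if voxel_noise_sd > 0:
                    series = series + rng.normal(0.0, voxel_noise_sd, n_vol)
                data[v, i, 0] = series
    affine = np.eye(4)
    img4d = nib.Nifti1Image(data, affine)
    labelmap = nib.Nifti1Image(labels, affine)
    code_map = {i + 1: r for i, r in enumerate(ds.regions)}
    return img4d, labelmap, code_map


# -- tabular I/O -----------------------------------------------------------

def _volume_columns(n_volumes: int) -> list[str]:
    return [f"v{i + 1:03d}" for i in range(n_volumes)]


def cohort_to_frame(cohort: Sequence[ParticipantDataset]) -> pd.DataFrame:
    """Long table: one row per (participant, group, condition, region, subregion)."""
    rows = []
    for ds in cohort:
        for cond, cube in ds.data.items():
            for i, region in enumerate(ds.regions):
                for j in range(cube.shape[1]):
                    row = {
                        "participant": ds.participant_id,
                        "group": ds.group,
                        "condition": cond,
                        "region": region,
                        "subregion": j + 1,
                    }
                    row.update(
                        dict(zip(_volume_columns(cube.shape[2]), cube[i, j]))
                    )
                    rows.append(row)
    return pd.DataFrame(rows)


def covariates_to_frame(cohort: Sequence[ParticipantDataset]) -> pd.DataFrame:
    rows = []
    for ds in cohort:
        row = {"participant": ds.participant_id, "group": ds.group}
        row.update(ds.covariates)
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_timecourses(
    frame: pd.DataFrame,
    participant: str,
    condition: str,
    choice: Mapping[str, int],
    regions: Sequence[str],
) -> np.ndarray:
    """(regions, volumes) matrix from the long table, one sub-region per region."""
    vcols = [c for c in frame.columns if c.startswith("v") and c[1:].isdigit()]
    sel = frame[(frame["participant"] == participant) & (frame["condition"] == condition)]
    rows = []
    for r in regions:
        sub = sel[(sel["region"] == r) & (sel["subregion"] == choice[r])]
        if len(sub) != 1:
            raise ValueError(
                f"expected exactly one row for {participant}/{condition}/{r}"
            )
        rows.append(sub[vcols].to_numpy(dtype=float)[0])
    return np.array(rows)
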