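"""Latent-input network model: forward generation and per-participant fitting.

The generative convention: each region's output series equals its summed
weighted input, ``O = A @ O + M @ L``, where ``A[r, s]`` is the signed
weight of the inter-region connection ``s -> r``, ``M`` holds latent-link
weights and ``L`` the latent time-courses.  Fitting alternates per-region
ordinary least squares on observed source series with closed-form latent
updates, recovering one signed weight per connection plus zero-mean,
unit-variance latent time-courses.
"""
from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .network import NetworkModel
from .synth import phase_randomize, stage_seed

__all__ = [
    "LatentSignal",
    "SAPMFit",
    "DerivedDShares",
    "NullReference",
    "StabilityError",
    "forward_model",
    "fit_sapm",
    "select_subregions",
    "fit_null_reference",
    "derived_D",
    "signal_decomposition",
]


class StabilityError(ValueError):
    """Raised when the inter-region weight matrix has spectral radius >= 1."""


@dataclass
class LatentSignal:
    """A fitted (or supplied) latent input time-course."""

    name: str
    series: np.ndarray

    def __post_init__(self) -> None:
        self.series = np.asarray(self.series, dtype=float)


@dataclass
class SAPMFit:
    """Per-participant fit: connection weights, latents, fit quality."""

    db: dict[tuple[str, str], float]
    latents: list[LatentSignal]
    subregion_choice: dict[str, int]
    r2_total: float
    r2_by_region: dict[str, float]
    sse: float
    n_iter: int
    converged: bool
    sse_history: list[float] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "db": {f"{s}->{t}": v for (s, t), v in self.db.items()},
            "latents": {l.name: l.series.tolist() for l in self.latents},
            "subregion_choice": self.subregion_choice,
            "r2_total": self.r2_total,
            "r2_by_region": self.r2_by_region,
            "sse": self.sse,
            "n_iter": self.n_iter,
            "converged": self.converged,
        }

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=1), encoding="utf-8")
        return path

    @classmethod
    def from_dict(cls, doc: dict) -> "SAPMFit":
        db = {tuple(k.split("->", 1)): float(v) for k, v in doc["db"].items()}
        latents = [LatentSignal(n, np.asarray(s)) for n, s in doc["latents"].items()]
        return cls(
            db=db,  # type: ignore[arg-type]
            latents=latents,
            subregion_choice={k: int(v) for k, v in doc["subregion_choice"].items()},
            r2_total=float(doc["r2_total"]),
            r2_by_region={k: float(v) for k, v in doc["r2_by_region"].items()},
            sse=float(doc["sse"]),
            n_iter=int(doc["n_iter"]),
            converged=bool(doc["converged"]),
        )

    @property
    def mean_region_r2(self) -> float:
        """Mean of per-region R^2; selection score for sub-region search.

        Unlike the pooled ``r2_total`` it is not dominated by high-variance
        regions, so attenuated sub-regions of low-variance regions still
        register as poor fits.
        """
        if not self.r2_by_region:
            return 0.0
        return float(np.mean(list(self.r2_by_region.values())))

    @classmethod
    def load(cls, path: str | Path) -> "SAPMFit":
        return cls.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))


@dataclass
class DerivedDShares:
    """Per-source normalized output shares derived from |db|."""

    shares: dict[tuple[str, str], float]


@dataclass
class NullReference:
    """Distribution of weights from fits to surrogate (phase-randomized) data."""

    db_samples: dict[tuple[str, str], np.ndarray]
    mean: dict[tuple[str, str], float] = field(default_factory=dict)
    sd: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for k, v in self.db_samples.items():
            v = np.asarray(v, dtype=float)
            self.db_samples[k] = v
            self.mean[k] = float(v.mean())
            self.sd[k] = float(v.std(ddof=1))


# -- forward model ---------------------------------------------------------

def _matrices(
    net: NetworkModel, db: Mapping[tuple[str, str], float]
) -> tuple[np.ndarray, np.ndarray]:
    regions = net.region_abbrevs
    ix = {a: i for i, a in enumerate(regions)}
    A = np.zeros((len(regions), len(regions)))
    for c in net.connections:
        A[ix[c.target], ix[c.source]] = db.get(c.key, 0.0)
    M = np.zeros((len(regions), len(net.latents)))
    for j, l in enumerate(net.latents):
        for t in l.targets:
            M[ix[t], j] = db.get((l.name, t), 0.0)
    return A, M


def forward_model(
    net: NetworkModel,
    db: Mapping[tuple[str, str], float],
    latents: Sequence[LatentSignal | tuple[str, np.ndarray]],
) -> np.ndarray:
    """Region output series ``O = (I - A)^-1 M L`` (regions x volumes).

    ``db`` maps (source, target) to weights for both inter-region and
    (latent, target) links.  Raises :class:`StabilityError` if the
    inter-region weight matrix has spectral radius >= 1.
    """
    A, M = _matrices(net, db)
    radius = float(np.max(np.abs(np.linalg.eigvals(A)))) if A.size else 0.0
    if radius >= 1.0:
        raise StabilityError(
            f"inter-region weight matrix is unstable (spectral radius {radius:.4f})"
        )
    by_name = {}
    for l in latents:
        name, series = (l.name, l.series) if isinstance(l, LatentSignal) else l
        by_name[name] = np.asarray(series, dtype=float)
    if not net.latents:
        n_vol = len(next(iter(by_name.values()))) if by_name else 0
        return np.zeros((len(net.regions), n_vol))
    L = np.array([by_name[l.name] for l in net.latents])
    return np.linalg.solve(np.eye(A.shape[0]) - A, M @ L)


# -- fitting ---------------------------------------------------------------

def _design_index(net: NetworkModel):
    """Per-region lists of source-region indices and latent indices."""
    regions = net.region_abbrevs
    ix = {a: i for i, a in enumerate(regions)}
    src = [[ix[s] for s in net.sources_of(r)] for r in regions]
    lat = [
        [j for j, l in enumerate(net.latents) if r in l.targets] for r in regions
    ]
    return src, lat


def _fit_once(
    obs: np.ndarray,
    net: NetworkModel,
    L0: np.ndarray,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, int, bool, list]:
    """One alternating-least-squares run from latent init ``L0``.

    Returns (B, M, L, sse, n_iter, converged, sse_history) where ``B[r, s]`` holds the
    weight of ``s -> r`` and ``M[r, j]`` the weight of latent j onto r.
    """
    n_regions, n_vol = obs.shape
    n_lat = L0.shape[0]
    src_ix, lat_ix = _design_index(net)
    B = np.zeros((n_regions, n_regions))
    M = np.zeros((n_regions, n_lat))
    L = L0.copy()
    prev_sse = np.inf
    sse = np.inf
    n_iter = 0
    converged = False
    history: list[float] = []
    for n_iter in range(1, max_iter + 1):
        # (i) per-region OLS on observed source series + current latents
        sse = 0.0
        for r in range(n_regions):
            cols = [obs[s] for s in src_ix[r]] + [L[j] for j in lat_ix[r]]
            if not cols:
                sse += float(obs[r] @ obs[r])
                continue
            X = np.column_stack(cols)
            coef, _, rank, _ = np.linalg.lstsq(X, obs[r], rcond=None)
            if rank < X.shape[1]:
                warnings.warn(
                    f"rank-deficient design for region {net.region_abbrevs[r]}; "
                    "minimum-norm solution used",
                    RuntimeWarning,
                    stacklevel=2,
                )
            B[r, src_ix[r]] = coef[: len(src_ix[r])]
            M[r, lat_ix[r]] = coef[len(src_ix[r]):]
            resid = obs[r] - X @ coef
            sse += float(resid @ resid)
        history.append(sse)
        # (ii) closed-form latent updates on target residuals
        base = obs - B @ obs  # residuals excluding all latent terms
        for j in range(n_lat):
            targets = [r for r in range(n_regions) if j in lat_ix[r]]
            w = M[targets, j]
            denom = float(w @ w)
            if denom <= 0:
                continue
            other = M[targets][:, [k for k in range(n_lat) if k != j]] @ np.delete(
                L, j, axis=0
            ) if n_lat > 1 else 0.0
            resid = base[targets] - other
            series = (w @ resid) / denom
            series = series - series.mean()
            sd = series.std()
            if sd > 0:
                M[:, j] *= sd
                series = series / sd
            L[j] = series
        # sign convention: weight onto first declared target non-negative
        for j, lat in enumerate(net.latents):
            first = net.region_abbrevs.index(lat.targets[0])
            if M[first, j] < 0:
                M[:, j] *= -1.0
                L[j] *= -1.0
        if prev_sse < np.inf and prev_sse > 0:
            if (prev_sse - sse) / prev_sse < tol:
                converged = True
                break
        elif prev_sse == 0.0 or sse == 0.0:
            converged = True
            break
        prev_sse = sse
    return B, M, L, sse, n_iter, converged, history


def _fit_to_result(
    obs: np.ndarray,
    net: NetworkModel,
    B: np.ndarray,
    M: np.ndarray,
    L: np.ndarray,
    sse: float,
    n_iter: int,
    converged: bool,
    choice: Mapping[str, int] | None,
    history: list[float] | None = None,
) -> SAPMFit:
    regions = net.region_abbrevs
    ix = {a: i for i, a in enumerate(regions)}
    db: dict[tuple[str, str], float] = {}
    for c in net.connections:
        db[c.key] = float(B[ix[c.target], ix[c.source]])
    for j, l in enumerate(net.latents):
        for t in l.targets:
            db[(l.name, t)] = float(M[ix[t], j])
    pred = B @ obs + M @ L
    sse = float(((obs - pred) ** 2).sum())
    r2_by_region = {}
    for r, name in enumerate(regions):
        tot = float(obs[r] @ obs[r])
        res = float(((obs[r] - pred[r]) ** 2).sum())
        r2_by_region[name] = max(0.0, 1.0 - res / tot) if tot > 0 else 0.0
    tot = float((obs**2).sum())
    r2_total = max(0.0, 1.0 - sse / tot) if tot > 0 else 0.0
    latents = [LatentSignal(l.name, L[j].copy()) for j, l in enumerate(net.latents)]
    return SAPMFit(
        db=db,
        latents=latents,
        subregion_choice=dict(choice or {r: 1 for r in regions}),
        r2_total=r2_total,
        r2_by_region=r2_by_region,
        sse=sse,
        n_iter=n_iter,
        converged=converged,
        sse_history=list(history or []),
    )


def fit_sapm(
    observed: np.ndarray,
    net: NetworkModel,
    *,
    max_iter: int = 200,
    tol: float = 1e-6,
    n_restarts: int = 5,
    seed: int = 0,
    latents_init: np.ndarray | None = None,
    subregion_choice: Mapping[str, int] | None = None,
) -> SAPMFit:
    """Fit connection weights and latent time-courses to observed series.

    ``observed`` is a (regions x volumes) matrix in network declaration
    order.  Alternating least squares: per-region OLS of each region's
    series on its observed source series plus its latent links, then
    closed-form latent updates over each latent's target residuals, with
    latents re-standardized (scale absorbed into the latent-link weights).
    Best of ``n_restarts`` random latent initializations by total SSE;
    an explicit ``latents_init`` replaces the first restart.
    """
    obs = np.asarray(observed, dtype=float)
    if not np.all(np.isfinite(obs)):
        raise ValueError("observed series contain non-finite values")
    if obs.ndim != 2 or obs.shape[0] != len(net.regions):
        raise ValueError(
            f"observed must be ({len(net.regions)}, volumes); got {obs.shape}"
        )
    if obs.shape[1] < 8:
        raise ValueError("need at least 8 volumes")
    obs = obs - obs.mean(axis=1, keepdims=True)
    n_lat = len(net.latents)
    n_vol = obs.shape[1]
    rng = np.random.default_rng(seed)
    best = None
    for restart in range(max(1, n_restarts)):
        if restart == 0 and latents_init is not None:
            L0 = np.asarray(latents_init, dtype=float).copy()
            if L0.shape != (n_lat, n_vol):
                raise ValueError("latents_init must be (n_latents, volumes)")
        else:
            L0 = rng.standard_normal((n_lat, n_vol))
        if n_lat:
            L0 = L0 - L0.mean(axis=1, keepdims=True)
            sd = L0.std(axis=1, keepdims=True)
            sd[sd == 0] = 1.0
            L0 = L0 / sd
        B, M, L, sse, n_iter, conv, hist = _fit_once(obs, net, L0, max_iter, tol)
        if best is None or sse < best[3] - 1e-12:
            best = (B, M, L, sse, n_iter, conv, hist)
    B, M, L, sse, n_iter, conv, hist = best
    return _fit_to_result(obs, net, B, M, L, sse, n_iter, conv, subregion_choice, hist)


# -- sub-region selection --------------------------------------------------

def _choice_series(candidates: np.ndarray, combo: Sequence[int]) -> np.ndarray:
    return np.array([candidates[r, c - 1] for r, c in enumerate(combo)])


def select_subregions(
    candidates: np.ndarray,
    net: NetworkModel,
    *,
    method: str = "auto",
    n_restarts: int = 5,
    seed: int = 0,
    max_sweeps: int = 10,
    fit_opts: Mapping | None = None,
) -> SAPMFit:
    """Choose one sub-region per region maximizing mean per-region R^2.

    ``candidates`` is (regions x n_subregions x volumes).  ``method`` is
    ``"exhaustive"``, ``"greedy"``, or ``"auto"`` (exhaustive when the
    network has <= 4 regions).  Greedy coordinate ascent sweeps regions in
    order, trying every candidate while holding the others fixed, from
    ``n_restarts`` random initial combinations (the first is all-ones).
    Ties break toward the lowest sub-region index.
    """
    candidates = np.asarray(candidates, dtype=float)
    n_regions, n_sub, _ = candidates.shape
    if n_regions != len(net.regions):
        raise ValueError("candidate region count does not match network")
    fit_opts = dict(fit_opts or {})
    fit_opts.setdefault("seed", stage_seed(seed, "subregion-fit"))
    regions = net.region_abbrevs

    def evaluate(combo: tuple[int, ...]) -> SAPMFit:
        choice = dict(zip(regions, combo))
        return fit_sapm(
            _choice_series(candidates, combo), net, subregion_choice=choice, **fit_opts
        )

    if method == "auto":
        method = "exhaustive" if n_regions <= 4 else "greedy"
    if method == "exhaustive":
        best = None
        for combo in itertools.product(range(1, n_sub + 1), repeat=n_regions):
            fit = evaluate(combo)
            if best is None or fit.mean_region_r2 > best.mean_region_r2 + 1e-12:
                best = fit
        assert best is not None
        return best
    if method != "greedy":
        raise ValueError(f"unknown method {method!r}")

    rng = np.random.default_rng(seed)
    best = None
    for restart in range(max(1, n_restarts)):
        if restart == 0:
            combo = tuple(1 for _ in range(n_regions))
        else:
            combo = tuple(int(v) for v in rng.integers(1, n_sub + 1, n_regions))
        current = evaluate(combo)
        for _ in range(max_sweeps):
            improved = False
            for r in range(n_regions):
                trial_best = current
                trial_combo = combo
                for c in range(1, n_sub + 1):
                    if c == combo[r]:
                        continue
                    cand = combo[:r] + (c,) + combo[r + 1:]
                    fit = evaluate(cand)
                    better = fit.mean_region_r2 > trial_best.mean_region_r2 + 1e-12
                    tie_lower = (
                        abs(fit.mean_region_r2 - trial_best.mean_region_r2) <= 1e-12
                        and cand[r] < trial_combo[r]
                    )
                    if better or tie_lower:
                        trial_best, trial_combo = fit, cand
                if trial_combo != combo:
                    combo, current = trial_combo, trial_best
                    improved = True
            if not improved:
                break
        if best is None or current.mean_region_r2 > best.mean_region_r2 + 1e-12:
            best = current
    assert best is not None
    return best


# -- null reference --------------------------------------------------------

def fit_null_reference(
    observed: np.ndarray,
    net: NetworkModel,
    n_null: int,
    seed: int = 0,
    *,
    fit_opts: Mapping | None = None,
) -> NullReference:
    """Weights from fits to phase-randomized surrogates of ``observed``."""
    if n_null < 2:
        raise ValueError("n_null must be >= 2")
    obs = np.asarray(observed, dtype=float)
    fit_opts = dict(fit_opts or {})
    keys = net.connection_keys(include_latent=True)
    samples: dict[tuple[str, str], list[float]] = {k: [] for k in keys}
    for i in range(n_null):
        surro = np.array(
            [
                phase_randomize(obs[r], seed=stage_seed(seed, f"null:{i}", r))
                for r in range(obs.shape[0])
            ]
        )
        opts = dict(fit_opts)
        opts.setdefault("seed", stage_seed(seed, "null-fit", i))
        fit = fit_sapm(surro, net, **opts)
        for k in keys:
            samples[k].append(fit.db[k])
    return NullReference(db_samples={k: np.array(v) for k, v in samples.items()})


# -- derived quantities ----------------------------------------------------

def derived_D(fit: SAPMFit, net: NetworkModel) -> DerivedDShares:
    """Fraction of |db| each outgoing connection carries from its source."""
    shares: dict[tuple[str, str], float] = {}
    for r in net.region_abbrevs:
        targets = net.targets_of(r)
        if not targets:
            continue
        mags = np.array([abs(fit.db[(r, t)]) for t in targets])
        total = mags.sum()
        if total > 0:
            vals = mags / total
        else:
            vals = np.full(len(targets), 1.0 / len(targets))
        for t, v in zip(targets, vals):
            shares[(r, t)] = float(v)
    return DerivedDShares(shares=shares)


def signal_decomposition(
    fit: SAPMFit, net: NetworkModel, region: str
) -> dict[str, object]:
    """Per-source input contributions to ``region`` under the fitted model.

    Returns ``{"contributions": {source: series}, "total_input": series,
    "output": series}`` where sources include latent inputs; contributions
    sum exactly to the modeled total input, which under the summed-input
    convention is also the region's modeled output series.
    """
    if region not in net.region_abbrevs:
        raise KeyError(region)
    O = forward_model(net, fit.db, fit.latents)
    ix = {a: i for i, a in enumerate(net.region_abbrevs)}
    contributions: dict[str, np.ndarray] = {}
    for s in net.sources_of(region):
        contributions[s] = fit.db[(s, region)] * O[ix[s]]
    for lname in net.latents_of(region):
        j = [l.name for l in net.latents].index(lname)
        contributions[lname] = fit.db[(lname, region)] * fit.latents[j].series
    n_vol = O.shape[1]
    total = np.zeros(n_vol)
    for series in contributions.values():
        total = total + series
    return {
        "contributions": contributions,
        "total_input": total,
        "output": O[ix[region]],
    }
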