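"""Ground-truth models and synthetic rasters emulating cortical recordings.

The original use case is 20 ms-binned binary activity of tens of cortical
neurons: low per-bin firing probabilities (a few percent) and weak pairwise
correlations. Since no recordings ship with the package, ground-truth RP
models are constructed directly — sparse N(1,1) projections with positive
λ, plus per-neuron bias ("field") projections adjusted until every
neuron's rate lands in a target range — and rasters are drawn from them
by Metropolis–Hastings. Once any
raster exists, the fit-then-sample route (train a model on it, sample from
the fit) is available through the training module.
"""
from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

from .errors import ConvergenceError, ParameterError
from .io import write_model, write_raster
from .model import (
    ENUMERATION_CAP,
    RPModel,
    enumerate_distribution,
    exact_model_expectations,
)
from .projections import Nonlinearity, ProjectionSet, build_sparse_projections
from .raster import SpikeRaster
from .sampler import ChainConfig, mh_sample

__all__ = [
    "make_ground_truth_model",
    "sample_synthetic_raster",
    "make_fixture_suite",
]

#: Default per-bin firing-probability target emulating sparse cortical
#: activity in 20 ms bins.
DEFAULT_RATE_RANGE = (0.01, 0.15)


def _neuron_rates(M: RPModel, seed: int) -> np.ndarray:
    if M.n_neurons <= ENUMERATION_CAP:
        return exact_model_expectations(M)["x_mean"]
    raster = mh_sample(M, ChainConfig(n_samples=20_000, seed=seed))
    return raster.neuron_marginals()


def make_ground_truth_model(
    n_neurons: int = 15,
    n_proj: int = 30,
    indegree: float = 5.0,
    nonlinearity: Nonlinearity | None = None,
    lambda_scale: float = 1.0,
    target_rate_range: tuple[float, float] = DEFAULT_RATE_RANGE,
    seed: int | None = None,
    max_attempts: int = 10,
) -> RPModel:
    """Construct a ground-truth RP model with realistic firing rates.

    Projections are drawn sparsely (Bernoulli ``indegree/n`` mask, N(1,1)
    weights, thresholds 1) and their λ as ``lambda_scale * |N(0,1)|``;
    they carry the pairwise correlations. If the resulting per-neuron
    rates fall outside ``target_rate_range``, single-input field
    projections (one per neuron) are appended and their λ adjusted by
    damped logit matching until every rate is in range; failing that the
    projections are redrawn (up to ``max_attempts`` times) before giving
    up with :class:`ConvergenceError`.

    With ``lambda_scale = 0`` the model is uniform and every rate is 0.5,
    so only ranges containing 0.5 are attainable. Passing
    ``target_rate_range=None`` skips the adjustment entirely and returns
    the raw random-projection model (no field projections, rates
    unconstrained) — useful when the experiment needs a pure sparse mask.
    """
    nl = nonlinearity or Nonlinearity("sigmoid", beta=2.0)
    rng = np.random.default_rng(seed)
    if target_rate_range is None:
        P = build_sparse_projections(
            n_neurons, n_proj, indegree, nl, seed=int(rng.integers(0, 2**31 - 1))
        )
        return RPModel(P, lambda_scale * np.abs(rng.standard_normal(n_proj)))
    lo, hi = target_rate_range
    if not (0.0 < lo < hi <= 0.55):
        raise ParameterError(
            f"target_rate_range must satisfy 0 < lo < hi <= 0.55, got {target_rate_range}"
        )
    for _attempt in range(max_attempts):
        p_seed = int(rng.integers(0, 2**31 - 1))
        r_seed = int(rng.integers(0, 2**31 - 1))
        P = build_sparse_projections(n_neurons, n_proj, indegree, nl, seed=p_seed)
        lam_rp = lambda_scale * np.abs(rng.standard_normal(n_proj))
        M = RPModel(P, lam_rp)
        rates = _neuron_rates(M, r_seed)
        if np.all((rates >= lo) & (rates <= hi)):
            return M
        M = _adjust_rates_with_fields(P, lam_rp, (lo, hi), rng, r_seed)
        if M is not None:
            return M
    raise ConvergenceError(
        f"could not place all neuron rates inside {target_rate_range} "
        f"after {max_attempts} attempts"
    )


def _adjust_rates_with_fields(
    P: ProjectionSet,
    lam_rp: np.ndarray,
    rate_range: tuple[float, float],
    rng: np.random.Generator,
    rate_seed: int,
    max_rounds: int = 60,
) -> RPModel | None:
    """Steer per-neuron rates into range with single-input field projections.

    One extra projection per neuron (mask = identity, weight 2, threshold
    1) acts as an individual activity bias; its λ is adjusted by damped
    logit matching toward per-neuron targets drawn inside the range, so
    the random projections keep carrying the pairwise correlations while
    the fields control the rates. Returns None if the loop fails.
    """
    lo, hi = rate_range
    n = P.n_neurons
    nl = P.nonlinearity
    field_mask = np.eye(n, dtype=np.uint8)
    field_weights = 2.0 * np.eye(n)
    full = ProjectionSet(
        mask=np.vstack([P.mask, field_mask]),
        weights=np.vstack([P.weights, field_weights]),
        thresholds=np.concatenate([P.thresholds, np.ones(n)]),
        nonlinearity=nl,
    )
    # energy gap a unit field λ puts on x_j = 1 vs 0
    gap = float(nl(np.array([1.0]))[0] - nl(np.array([-1.0]))[0])
    width = hi - lo
    targets = rng.uniform(lo + 0.25 * width, hi - 0.25 * width, size=n)
    t_logit = np.log(targets / (1.0 - targets))
    lam_field = np.zeros(n)
    for _ in range(max_rounds):
        M = RPModel(full, np.concatenate([lam_rp, lam_field]))
        rates = np.clip(_neuron_rates(M, rate_seed), 1e-6, 1 - 1e-6)
        if np.all((rates >= lo) & (rates <= hi)):
            return M
        r_logit = np.log(rates / (1.0 - rates))
        lam_field += 0.7 * (r_logit - t_logit) / gap
    return None


def sample_synthetic_raster(
    M: RPModel,
    n_train: int,
    n_test: int | None = None,
    seed: int = 0,
) -> tuple[SpikeRaster, SpikeRaster]:
    """Draw a raster from the model and split it into train/test.

    The default test size is ``n_train / 4`` (the conventional 4:1
    train:test proportion, e.g. 160k/40k samples). The two rasters are
    disjoint segments of a single chain.
    """
    if n_train < 1:
        raise ParameterError("n_train must be >= 1")
    if n_test is None:
        n_test = int(round(n_train / 4))
    if n_test < 1:
        raise ParameterError("n_test must be >= 1")
    raster = mh_sample(M, ChainConfig(n_samples=n_train + n_test, seed=seed))
    return raster[:n_train], raster[n_train:]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def make_fixture_suite(out_dir, seed: int = 0) -> dict:
    """Write the canonical small test cases and return their manifest.

    Cases: (a) the n=2 closed-form model (single Heaviside projection
    a=(1,1), θ=1, λ=ln 3, for which Z=2 analytically); (b) n=8 and n=12
    random sigmoid models with their exact enumeration tables; (c) a
    20-neuron sparse-regime dataset (indegree 5, θ=1, N(1,1) weights)
    with a sampled raster. Everything is regenerable bit-identically from
    the seed; the manifest lists each file's SHA-256.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    files: dict[str, str] = {}

    def record(name: str) -> None:
        files[name] = _sha256(out / name)

    # (a) closed-form two-neuron model
    P2 = ProjectionSet(
        mask=np.array([[1, 1]]),
        weights=np.array([[1.0, 1.0]]),
        thresholds=np.array([1.0]),
        nonlinearity=Nonlinearity("heaviside"),
    )
    write_model(RPModel(P2, np.array([np.log(3.0)])), out / "n2_closed_form.model.json")
    record("n2_closed_form.model.json")

    # (b) random models with enumeration oracle tables
    for n, n_proj, indeg, name in ((8, 10, 3.0, "n8_random"), (12, 15, 4.0, "n12_random")):
        M = make_ground_truth_model(
            n_neurons=n,
            n_proj=n_proj,
            indegree=indeg,
            lambda_scale=1.0,
            target_rate_range=(0.01, 0.25),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        write_model(M, out / f"{name}.model.json")
        record(f"{name}.model.json")
        _, probs = enumerate_distribution(M)
        table = "\n".join(
            f"{k},{float(probs[k])!r}" for k in range(probs.size)
        )
        (out / f"{name}.enumeration.csv").write_text(
            "pattern_index,probability\n" + table + "\n"
        )
        record(f"{name}.enumeration.csv")

    # (c) 20-neuron sparse-regime model and raster
    M20 = make_ground_truth_model(
        n_neurons=20,
        n_proj=30,
        indegree=5.0,
        lambda_scale=1.0,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    write_model(M20, out / "n20_sparse_regime.model.json")
    record("n20_sparse_regime.model.json")
    train, test = sample_synthetic_raster(
        M20, 16_000, 4_000, seed=int(rng.integers(0, 2**31 - 1))
    )
    write_raster(train, out / "n20_sparse_regime.train.csv")
    write_raster(test, out / "n20_sparse_regime.test.csv")
    record("n20_sparse_regime.train.csv")
    record("n20_sparse_regime.test.csv")

    manifest = {"version": 1, "seed": seed, "files": files}
    (out / "manifest.json").write_text(
        json.dumps(manifest, sort_keys=True, indent=1) + "\n"
    )
    return manifest
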