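"""Random cross-validation and prediction-accuracy metrics.

The hold-out scheme masks whole (environment, line) cells: when a cell is in
the test set, ALL its traits are missing, and lines may disappear from some
environments entirely, but every line is guaranteed at least one training
environment.  Partitions are independent random draws (not folds); metrics
(Pearson correlation, mean squared error of prediction) are computed per
trait-environment cell within each partition, then averaged across
partitions with a standard error ``SD / sqrt(k)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import ChainConfig, MTMEDataset, build_design
from .gibbs import default_hyperparams, run_bmtme
from .kernels import Kinship
from .svd_approx import fit_bmtme_approx_cv

__all__ = ["CVPartitionSet", "make_partitions", "pearson_cor", "msep",
           "summarize_cv", "chain_diagnostics", "cross_validate"]


@dataclass
class CVPartitionSet:
    """k independent train/test splits over the (environment, line) cells."""

    k: int
    test_fraction: float
    assignments: list[np.ndarray]   # per partition: boolean test mask over rows
    seed: int


def make_partitions(dataset: MTMEDataset, k: int, test_fraction: float,
                    seed: int, max_attempts: int = 1000) -> CVPartitionSet:
    """Draw k random test sets of round(test_fraction * n) cells each.

    A draw that leaves some line with zero training cells is rejected and
    redrawn (bounded attempts).  Reproducible from the seed.
    """
    if not 0 < test_fraction <= 0.5:
        raise ValueError("test_fraction must be in (0, 0.5]")
    n = dataset.n_rows
    n_test = int(round(test_fraction * n))
    if n_test < 1:
        raise ValueError("test fraction leaves an empty test set")
    line_of_row = np.array([dataset.line_ids.index(l) for _, l in dataset.row_index])
    counts = np.bincount(line_of_row, minlength=dataset.n_lines)
    if (counts <= 1).any() and test_fraction > 0:
        # a line observed once can never be held out; feasible only if enough
        # multi-environment lines exist to fill the test set
        if (counts > 1).sum() == 0:
            raise ValueError("no line has more than one environment; the "
                             "coverage constraint is infeasible")
    rng = np.random.default_rng(seed)
    assignments = []
    for _ in range(k):
        for attempt in range(max_attempts):
            idx = rng.choice(n, size=n_test, replace=False)
            mask = np.zeros(n, dtype=bool)
            mask[idx] = True
            train_counts = np.bincount(line_of_row[~mask], minlength=dataset.n_lines)
            if (train_counts > 0).all():
                assignments.append(mask)
                break
        else:
            raise RuntimeError(f"could not satisfy the line-coverage constraint "
                               f"in {max_attempts} attempts")
    return CVPartitionSet(k=k, test_fraction=test_fraction,
                          assignments=assignments, seed=seed)


def pearson_cor(obs: np.ndarray, pred: np.ndarray) -> float:
    """Sample Pearson correlation; NaN when either vector has zero variance."""
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if obs.shape != pred.shape or obs.size < 2:
        raise ValueError("need two equal-length vectors of size >= 2")
    if np.std(obs) == 0 or np.std(pred) == 0:
        return float("nan")
    return float(np.corrcoef(obs, pred)[0, 1])


def msep(obs: np.ndarray, pred: np.ndarray) -> float:
    """Mean squared error of prediction."""
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("need two equal-length vectors")
    return float(np.mean((obs - pred) ** 2))


def summarize_cv(records: pd.DataFrame) -> pd.DataFrame:
    """Per trait-environment summary of per-partition predictions.

    ``records`` has columns (partition, env, line, trait, observed, predicted).
    Metrics are computed within each partition on that cell's test
    observations, then averaged across partitions; the output mirrors a
    (Cor, SE, MSEP, SE) table with one row per env x trait cell plus an
    unweighted grand-average row.
    """
    needed = {"partition", "env", "trait", "observed", "predicted"}
    if not needed.issubset(records.columns):
        raise ValueError(f"records must have columns {sorted(needed)}")
    if records["partition"].nunique() < 2:
        raise ValueError("need at least 2 partitions to report standard errors")
    rows = []
    for (env, trait), cell in records.groupby(["env", "trait"], sort=True):
        cors, errs = [], []
        for _, part in cell.groupby("partition"):
            if len(part) < 2:
                continue   # cell absent (or singleton) in this partition
            c = pearson_cor(part["observed"].to_numpy(), part["predicted"].to_numpy())
            if np.isfinite(c):
                cors.append(c)
            errs.append(msep(part["observed"].to_numpy(), part["predicted"].to_numpy()))
        cors, errs = np.array(cors), np.array(errs)
        rows.append({
            "env": env, "trait": trait,
            "cor_mean": cors.mean() if cors.size else np.nan,
            "cor_se": cors.std() / np.sqrt(cors.size) if cors.size > 1 else np.nan,
            "msep_mean": errs.mean() if errs.size else np.nan,
            "msep_se": errs.std() / np.sqrt(errs.size) if errs.size > 1 else np.nan,
        })
    out = pd.DataFrame(rows)
    avg = {"env": "Average", "trait": "",
           "cor_mean": out["cor_mean"].mean(), "cor_se": out["cor_se"].mean(),
           "msep_mean": out["msep_mean"].mean(), "msep_se": out["msep_se"].mean()}
    return pd.concat([out, pd.DataFrame([avg])], ignore_index=True)


def chain_diagnostics(draws: np.ndarray, names: list[str] | None = None) -> pd.DataFrame:
    """ESS, lag-1 autocorrelation and split R-hat per parameter column.

    ``draws`` is (n_draws, n_params) (a single chain is split in half for the
    R-hat).  Constant chains are flagged degenerate (NaN diagnostics).
    """
    import arviz as az

    draws = np.atleast_2d(np.asarray(draws, dtype=float))
    if draws.ndim == 1:
        draws = draws[:, None]
    if draws.shape[0] < 100:
        raise ValueError("need at least 100 stored draws for diagnostics")
    S, P = draws.shape
    if names is None:
        names = [f"param{p}" for p in range(P)]
    half = S // 2
    rows = []
    for p in range(P):
        x = draws[:, p]
        if np.std(x) == 0:
            rows.append({"param": names[p], "ess": np.nan, "acf1": np.nan,
                         "rhat": np.nan, "degenerate": True})
            continue
        two = np.vstack([x[:half], x[half:2 * half]])
        ess = float(az.ess(az.convert_to_dataset(x[None, :])).x)
        rhat = float(az.rhat(az.convert_to_dataset(two)).x)
        xc = x - x.mean()
        acf1 = float(xc[:-1] @ xc[1:] / (xc @ xc))
        rows.append({"param": names[p], "ess": ess, "acf1": acf1,
                     "rhat": rhat, "degenerate": False})
    return pd.DataFrame(rows)


def cross_validate(dataset: MTMEDataset, G: Kinship | np.ndarray,
                   partitions: CVPartitionSet, chain: ChainConfig,
                   model: str = "bmtme",
                   nu_t: float | None = None, nu_E: float | None = None,
                   nu_e: float | None = None) -> pd.DataFrame:
    """Run one model over all partitions; returns the long prediction table.

    ``model`` is ``"bmtme"`` (full multi-trait sampler, Thompson variant,
    held-out cells imputed by augmentation) or ``"approx"`` (SVD four-step
    method with a training-set SVD).  Each partition gets a deterministic
    sub-seed of ``chain.seed``.
    """
    if model not in ("bmtme", "approx"):
        raise ValueError("model must be 'bmtme' or 'approx'")
    design = build_design(dataset)
    seeds = np.random.SeedSequence(chain.seed).spawn(partitions.k)
    records = []
    for p, test_mask in enumerate(partitions.assignments):
        sub = ChainConfig(n_iter=chain.n_iter, burn_in=chain.burn_in, thin=chain.thin,
                          seed=int(seeds[p].generate_state(1)[0] % (2 ** 31)))
        if model == "bmtme":
            masked = MTMEDataset(dataset.env_ids, dataset.line_ids,
                                 np.where(test_mask[:, None], np.nan, dataset.Y),
                                 dataset.trait_names, dataset.row_index)
            hyper = default_hyperparams(masked, nu_t=nu_t, nu_E=nu_E, nu_e=nu_e)
            post = run_bmtme(masked, design, G, hyper, sub, sampler="thompson")
            pred = post.fitted
        else:
            est = fit_bmtme_approx_cv(dataset, design, G, sub, test_rows=test_mask)
            pred = est.Y_hat
        for r in np.flatnonzero(test_mask):
            env, line = dataset.row_index[r]
            for l, trait in enumerate(dataset.trait_names):
                records.append({"partition": p, "env": env, "line": line,
                                "trait": trait, "observed": dataset.Y[r, l],
                                "predicted": pred[r, l]})
    return pd.DataFrame.from_records(records)
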