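"""QSAR model selection linking MD descriptors to enzyme kinetics.

The protocol maps trajectory-averaged binding descriptors (interaction
energies in kJ/mol, accessible areas in nm²) to the log10 of the
Michaelis–Menten parameters kcat (min⁻¹), Km (µM) and the catalytic
efficiency kcat/Km (min⁻¹µM⁻¹) of an enzyme variant panel:

1. a Pearson-R² screen of every descriptor against every log-response;
2. single-predictor ordinary least squares; the best single model per
   response is accepted if its fit R² clears a bar (default 0.65);
3. for responses without an acceptable single model, two-predictor OLS,
   guarded by an *independence* screen (predictor–predictor R² must not
   exceed 0.5 by default) and a *redundancy* screen (the double model
   must improve on the better of its two single models by at least 0.05
   R² units by default);
4. leave-one-out cross-validation of every accepted model: the mean ±
   SD of per-fold training R², and the mean square error of the
   held-out log10 predictions;
5. prediction of kcat and kcat/Km for an uncharacterised variant from
   its descriptors, with Km recovered as kcat ÷ (kcat/Km).

All responses are modelled on the log10 scale and all fits are
unweighted OLS solved by the normal equations (via a least-squares
solve); descriptor standard deviations are carried for reporting only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

RESPONSES = ("kcat", "Km", "kcat_over_Km")

#: Descriptor columns eligible as predictors, in screening order.
DESCRIPTOR_COLUMNS = ("SAS_NADP", "SAS_hPGS", "IE_P_hP", "IE_N_hP")


@dataclass
class QSARConfig:
    """Selection-protocol thresholds (all on the R² scale)."""

    min_single_r2: float = 0.65        # acceptance bar for a single model
    min_double_r2: float = 0.65        # acceptance bar for a double model
    independence_max_r2: float = 0.5   # max allowed predictor–predictor R²
    redundancy_min_gain: float = 0.05  # required R² gain over best single
    recompute_ratio: bool = False      # derive kcat/Km from kcat and Km
                                       # instead of using the tabulated ratio


@dataclass
class LOOStats:
    """Leave-one-out summary: fold-training R² spread and held-out MSE."""

    mean_fold_r2: float
    sd_fold_r2: float
    mse: float
    n_folds: int


@dataclass
class QSARModel:
    """A fitted (or rejected) linear model for one log10 response."""

    response: str
    predictors: tuple[str, ...]
    intercept: float | None
    slopes: dict[str, float] | None
    fit_r2: float | None
    status: str  # accepted | rejected_correlated_predictors |
                 # rejected_redundant | rejected_low_R2
    diagnostics: dict = field(default_factory=dict)
    loo: LOOStats | None = None

    def evaluate(self, values: dict[str, float], rounded: bool = False) -> float:
        """Model value (log10 response) at the given descriptor values.

        With ``rounded`` the coefficients are first rounded to tabulation
        precision (slopes 4 decimals, intercept 3), reproducing what a
        reader of the printed equations would compute.
        """
        if self.status != "accepted" or self.intercept is None:
            raise ValueError("cannot evaluate a rejected model")
        b0 = round(self.intercept, 3) if rounded else self.intercept
        y = b0
        for name in self.predictors:
            b = self.slopes[name]
            y += (round(b, 4) if rounded else b) * values[name]
        return y


@dataclass
class PredictionResult:
    """Predicted kinetics for one variant, with changes vs wild type."""

    variant: str
    kcat: float
    kcat_over_km: float
    km: float
    pct_change_kcat: float | None
    pct_change_km: float | None
    pct_change_efficiency: float | None
    extrapolation: bool = False


def load_table2() -> pd.DataFrame:
    """Bundled variant panel: descriptors plus kinetics, one row per variant.

    Eight rows carry measured kinetics; the L213Q row is prediction-only
    (``measured`` False).  ``kcat_over_Km`` is the tabulated ratio column.
    """
    with resources.files("md2qsar.data").joinpath("table2.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    df["measured"] = df["measured"].astype(bool)
    return df


def load_table1() -> pd.DataFrame:
    """Bundled long-trajectory descriptor summary for WT vs L213Q."""
    with resources.files("md2qsar.data").joinpath("table1.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def _log_response(data: pd.DataFrame, response: str, config: QSARConfig) -> np.ndarray:
    if response == "kcat_over_Km" and config.recompute_ratio:
        return np.log10(data["kcat"].to_numpy() / data["Km"].to_numpy())
    return np.log10(data[response].to_numpy(dtype=float))


def _measured(data: pd.DataFrame) -> pd.DataFrame:
    return data.loc[data["measured"]].reset_index(drop=True)


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """Least-squares fit with intercept; returns (coefficients, R²).

    A constant response fitted exactly (zero total and residual sum of
    squares, as happens in two-point leave-one-out folds) takes R² = 1
    by convention; a constant response fitted imperfectly takes R² = 0.
    """
    design = np.column_stack([np.ones(len(y)), x])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    fitted = design @ coef
    sst = float(((y - y.mean()) ** 2).sum())
    ssr = float(((y - fitted) ** 2).sum())
    if sst == 0.0:
        scale = max(1.0, float((y ** 2).sum()))
        return coef, 1.0 if ssr <= 1e-12 * scale else 0.0
    return coef, 1.0 - ssr / sst


def pearson_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation (identical to single-OLS fit R²)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    vx = x - x.mean()
    vy = y - y.mean()
    denom = float(np.sqrt((vx ** 2).sum() * (vy ** 2).sum()))
    if denom == 0.0:
        raise ValueError("zero variance input")
    return float((vx @ vy) ** 2) / denom ** 2


def correlation_matrix(
    data: pd.DataFrame, config: QSARConfig = QSARConfig()
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """R² screen of descriptors vs log-responses, plus descriptor block.

    Returns ``(descriptor × response, descriptor × descriptor)`` R²
    tables over the measured variants.  Requires at least three measured
    variants.
    """
    m = _measured(data)
    if len(m) < 3:
        raise ValueError("need at least 3 measured variants")
    descs = [c for c in DESCRIPTOR_COLUMNS if c in m.columns]
    resp = pd.DataFrame(index=descs, columns=list(RESPONSES), dtype=float)
    for d in descs:
        for r in RESPONSES:
            resp.loc[d, r] = pearson_r2(m[d].to_numpy(), _log_response(m, r, config))
    cross = pd.DataFrame(index=descs, columns=descs, dtype=float)
    for d1 in descs:
        for d2 in descs:
            cross.loc[d1, d2] = pearson_r2(m[d1].to_numpy(), m[d2].to_numpy())
    return resp, cross


def fit_single(
    data: pd.DataFrame,
    descriptor: str,
    response: str,
    config: QSARConfig = QSARConfig(),
) -> QSARModel:
    """OLS of a log10 response on one descriptor's trajectory mean."""
    m = _measured(data)
    if len(m) < 3:
        raise ValueError("need at least 3 measured variants")
    x = m[descriptor].to_numpy(dtype=float)
    if x.std() == 0.0:
        raise ValueError(f"descriptor {descriptor} has zero variance")
    y = _log_response(m, response, config)
    coef, r2 = _ols(x, y)
    return QSARModel(
        response=response,
        predictors=(descriptor,),
        intercept=float(coef[0]),
        slopes={descriptor: float(coef[1])},
        fit_r2=r2,
        status="accepted",
    )


def fit_double(
    data: pd.DataFrame,
    d1: str,
    d2: str,
    response: str,
    config: QSARConfig = QSARConfig(),
) -> QSARModel:
    """Two-predictor OLS guarded by independence and redundancy screens.

    The predictors must be mutually independent (pairwise R² within
    ``independence_max_r2``) and the double fit must add at least
    ``redundancy_min_gain`` R² units over the better of the two single
    fits, otherwise the model is returned with a rejected status and
    the triggering diagnostic.
    """
    if d1 == d2:
        raise ValueError("the two predictors must differ")
    m = _measured(data)
    if len(m) < 4:
        raise ValueError("need at least 4 measured variants")
    x1 = m[d1].to_numpy(dtype=float)
    x2 = m[d2].to_numpy(dtype=float)
    cross_r2 = pearson_r2(x1, x2)
    if cross_r2 > config.independence_max_r2:
        return QSARModel(
            response=response, predictors=(d1, d2), intercept=None,
            slopes=None, fit_r2=None, status="rejected_correlated_predictors",
            diagnostics={"predictor_r2": cross_r2},
        )
    y = _log_response(m, response, config)
    coef, r2 = _ols(np.column_stack([x1, x2]), y)
    best_single = max(
        fit_single(data, d1, response, config).fit_r2,
        fit_single(data, d2, response, config).fit_r2,
    )
    if r2 - best_single < config.redundancy_min_gain:
        return QSARModel(
            response=response, predictors=(d1, d2), intercept=None,
            slopes=None, fit_r2=r2, status="rejected_redundant",
            diagnostics={"best_single_r2": best_single, "gain": r2 - best_single},
        )
    return QSARModel(
        response=response,
        predictors=(d1, d2),
        intercept=float(coef[0]),
        slopes={d1: float(coef[1]), d2: float(coef[2])},
        fit_r2=r2,
        status="accepted",
        diagnostics={"predictor_r2": cross_r2, "best_single_r2": best_single},
    )


def loo_validate(
    model: QSARModel, data: pd.DataFrame, config: QSARConfig = QSARConfig()
) -> LOOStats:
    """Leave-one-out cross-validation of an accepted model.

    Each variant is held out in turn and the model refitted on the
    remaining ones; the refit's training R² feeds the mean ± SD summary
    and the held-out log10 prediction feeds the mean square error
    ``(1/n)Σ(observed − predicted)²``.  Folds whose reduced design is
    degenerate (zero predictor variance) are excluded with a warning.
    """
    import warnings

    m = _measured(data)
    min_n = 3 if len(model.predictors) == 1 else 4
    if len(m) < min_n:
        raise ValueError(f"need at least {min_n} measured variants")
    y = _log_response(m, model.response, config)
    x = m[list(model.predictors)].to_numpy(dtype=float)

    fold_r2, sq_err = [], []
    for i in range(len(m)):
        keep = np.ones(len(m), dtype=bool)
        keep[i] = False
        xt, yt = x[keep], y[keep]
        if any(xt[:, j].std() == 0.0 for j in range(xt.shape[1])):
            warnings.warn(f"fold {i}: zero predictor variance, excluded")
            continue
        coef, r2 = _ols(xt, yt)
        fold_r2.append(r2)
        pred = coef[0] + x[i] @ coef[1:]
        sq_err.append((y[i] - pred) ** 2)
    stats = LOOStats(
        mean_fold_r2=float(np.mean(fold_r2)),
        sd_fold_r2=float(np.std(fold_r2)),
        mse=float(np.mean(sq_err)),
        n_folds=len(fold_r2),
    )
    model.loo = stats
    return stats


def build_models(
    data: pd.DataFrame, config: QSARConfig = QSARConfig()
) -> tuple[dict[str, QSARModel | None], list[QSARModel]]:
    """Run the full selection protocol over every response.

    For each response, every descriptor is tried as a single predictor;
    the best single fit is accepted when its R² clears
    ``min_single_r2``.  Responses left without a single model escalate
    to all descriptor pairs, subject to the independence and redundancy
    screens and the ``min_double_r2`` bar.  Accepted models get LOO
    statistics attached.

    Returns ``(accepted-by-response, provenance log of every model
    tried)``; a response with no acceptable model maps to ``None``
    (reported as unmodelled).
    """
    m = _measured(data)
    descs = [c for c in DESCRIPTOR_COLUMNS if c in m.columns and m[c].notna().all()]
    accepted: dict[str, QSARModel | None] = {}
    log: list[QSARModel] = []

    for response in RESPONSES:
        singles = []
        for d in descs:
            mod = fit_single(data, d, response, config)
            if mod.fit_r2 < config.min_single_r2:
                mod.status = "rejected_low_R2"
            singles.append(mod)
            log.append(mod)
        ok_singles = [s for s in singles if s.status == "accepted"]
        if ok_singles:
            best = max(ok_singles, key=lambda s: s.fit_r2)
            loo_validate(best, data, config)
            accepted[response] = best
            continue

        doubles = []
        for i in range(len(descs)):
            for j in range(i + 1, len(descs)):
                mod = fit_double(data, descs[i], descs[j], response, config)
                if mod.status == "accepted" and mod.fit_r2 < config.min_double_r2:
                    mod.status = "rejected_low_R2"
                doubles.append(mod)
                log.append(mod)
        ok_doubles = [d for d in doubles if d.status == "accepted"]
        if ok_doubles:
            best = max(ok_doubles, key=lambda d: d.fit_r2)
            loo_validate(best, data, config)
            accepted[response] = best
        else:
            accepted[response] = None
    return accepted, log


def predict_variant(
    model_kcat: QSARModel,
    model_efficiency: QSARModel,
    descriptors: dict[str, float],
    wild_type: dict[str, float] | None = None,
    training_data: pd.DataFrame | None = None,
    rounded: bool = True,
) -> PredictionResult:
    """Predict kcat, kcat/Km and Km for a new variant from its descriptors.

    kcat and kcat/Km come from exponentiating the two models at the
    variant's descriptor values; Km is their quotient, which keeps the
    three predictions internally consistent.  With ``rounded`` (the
    default) the models are evaluated at tabulation-precision
    coefficients, matching what the printed equations yield.  When the
    training data are supplied, descriptor values outside the training
    range flag the result as an extrapolation.
    """
    log_kcat = model_kcat.evaluate(descriptors, rounded=rounded)
    log_eff = model_efficiency.evaluate(descriptors, rounded=rounded)
    kcat = 10.0 ** log_kcat
    eff = 10.0 ** log_eff
    km = kcat / eff

    extrapolation = False
    if training_data is not None:
        m = _measured(training_data)
        used = set(model_kcat.predictors) | set(model_efficiency.predictors)
        for name in used:
            lo, hi = m[name].min(), m[name].max()
            if not (lo <= descriptors[name] <= hi):
                extrapolation = True

    pct_kcat = pct_km = pct_eff = None
    if wild_type is not None:
        pct_kcat = 100.0 * (kcat - wild_type["kcat"]) / wild_type["kcat"]
        pct_eff = 100.0 * (eff - wild_type["kcat_over_Km"]) / wild_type["kcat_over_Km"]
        pct_km = 100.0 * (km - wild_type["Km"]) / wild_type["Km"]

    return PredictionResult(
        variant=str(descriptors.get("variant", "?")),
        kcat=kcat, kcat_over_km=eff, km=km,
        pct_change_kcat=pct_kcat, pct_change_km=pct_km,
        pct_change_efficiency=pct_eff,
        extrapolation=extrapolation,
    )
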