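"""Fishing / non-fishing trip classification.

Two tiers mirror how the problem decomposes in practice: an ordered set
of decision rules settles the unambiguous cases (ticket-matched trips
are fishing; corridor-only transits, calendar-flagged charters and trips
with no slow records away from port are not), and a penalized logistic
GAM predicts the remainder from trip-level movement features:

    logit(p(fishing)) = s(ln duration, avesp) + s(sddif) + s(sdsp)
                        + season_j + start_k + end_l

where avesp is the mean speed of records > 10 nmi from port moving > 0 kn,
sddif the SD of consecutive-speed differences among records at fishing
speeds (0-5 kn), and sdsp the SD of speed away from port.  Smooth terms
use penalized B-splines; the bivariate duration-by-speed surface is
approximated by the two marginal smoothers plus a linear interaction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
import statsmodels.api as sm
from sklearn.model_selection import train_test_split
from statsmodels.gam.api import BSplines, GLMGam
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .synthetic_fleet import PortSet
from .ticket_matching import season_of

log = logging.getLogger(__name__)

FISHING_SPEED_MAX_KN = 5.0
FAR_FROM_PORT_NMI = 10.0

_SMOOTH_COLS = ("ln_duration", "avesp", "sddif", "sdsp")
_FACTOR_COLS = ("season", "start_region", "end_region")


def compute_features(trips, records: pd.DataFrame, ports: PortSet,
                     fishing_areas=None, vessel_sizes=None) -> pd.DataFrame:
    """Trip-level predictor features, one row per trip.

    Each feature is computed on its own record subset; features whose
    subset is empty are NaN with a companion ``<name>_missing`` flag.
    ``avgspstat`` and ``size`` are candidate covariates kept for
    completeness; the default model omits them.
    """
    speed = records["speed_kn"].to_numpy(dtype=float)
    dist_port = records["dist_port_nmi"].to_numpy(dtype=float)
    areas = records["stat_area"].to_numpy()
    ts = records["timestamp"].to_numpy()
    fishing_areas = set(fishing_areas or ())
    rows = []
    for trip in trips:
        # features are per-trip aggregates over the time-ordered records,
        # invariant to how the index happens to be arranged
        pos = trip.record_index[np.argsort(ts[trip.record_index],
                                           kind="stable")]
        sp = speed[pos]
        far = (dist_port[pos] > FAR_FROM_PORT_NMI) & (sp > 0)
        far_sp = sp[far & np.isfinite(sp)]
        slow = np.isfinite(sp) & (sp >= 0) & (sp <= FISHING_SPEED_MAX_KN)
        # consecutive-record speed differences within the fishing band
        both_slow = slow[1:] & slow[:-1]
        diffs = np.diff(sp)[both_slow]
        instat = np.array([a in fishing_areas for a in areas[pos]]) \
            & np.isfinite(sp)
        row = {
            "trip_id": trip.trip_id,
            "duration": trip.duration_min,
            "avesp": far_sp.mean() if far_sp.size else np.nan,
            "sdsp": far_sp.std(ddof=1) if far_sp.size > 1 else np.nan,
            "sddif": diffs.std(ddof=1) if diffs.size > 1 else np.nan,
            "avedif": np.abs(diffs).mean() if diffs.size else np.nan,
            "avgspstat": sp[instat].mean() if instat.any() else np.nan,
            "season": season_of(trip.first_record_time),
            "start_region": (ports[trip.start_port].region
                             if trip.start_port in (ports.ids if ports else [])
                             else "Other"),
            "end_region": (ports[trip.end_port].region
                           if trip.end_port in (ports.ids if ports else [])
                           else "Other"),
            "size": (vessel_sizes or {}).get(trip.vessel_id, np.nan),
        }
        for f in ("avesp", "sdsp", "sddif", "avedif", "avgspstat"):
            row[f"{f}_missing"] = not np.isfinite(row[f])
        rows.append(row)
    return pd.DataFrame(rows).set_index("trip_id")


# ---------------------------------------------------------------------------
# Decision rules
# ---------------------------------------------------------------------------

@dataclass
class RuleConfig:
    """Configurable ordered decision rules (first match wins)."""

    corridors: list = field(default_factory=list)  # shapely polygons
    #: (vessel_id, start_date, end_date) entries for research charters /
    #: tendering assignments known from calendars
    nonfishing_calendar: list = field(default_factory=list)


def apply_decision_rules(trips, records: pd.DataFrame,
                         config: RuleConfig | None = None) -> dict:
    """Label trips by ordered rules; returns {trip_id: 'fishing'|'nonfishing'}.

    Unmatched trips are absent from the result (left for the model).
    Rules, in order: a matched fish ticket implies fishing; a trip lying
    entirely inside declared transit corridors is non-fishing; a
    calendar-flagged charter/tender period is non-fishing; a trip with no
    records at fishing speeds (0-5 kn) beyond 10 nmi from port is
    non-fishing.
    """
    config = config or RuleConfig()
    labels = {}
    lat = records["lat"].to_numpy()
    lon = records["lon"].to_numpy()
    speed = records["speed_kn"].to_numpy(dtype=float)
    dist_port = records["dist_port_nmi"].to_numpy(dtype=float)
    for poly in config.corridors:
        shapely.prepare(poly)
    for trip in trips:
        pos = trip.record_index
        if trip.ticket_ids:
            labels[trip.trip_id] = "fishing"
            continue
        if config.corridors:
            inside = np.zeros(len(pos), dtype=bool)
            for poly in config.corridors:
                inside |= shapely.intersects_xy(poly, lon[pos], lat[pos])
            if inside.all():
                labels[trip.trip_id] = "nonfishing"
                continue
        if any(v == trip.vessel_id
               and pd.Timestamp(a) <= trip.first_record_time <= pd.Timestamp(b)
               for v, a, b in config.nonfishing_calendar):
            labels[trip.trip_id] = "nonfishing"
            continue
        sp = speed[pos]
        slow_far = (np.isfinite(sp) & (sp >= 0)
                    & (sp <= FISHING_SPEED_MAX_KN)
                    & (dist_port[pos] > FAR_FROM_PORT_NMI))
        if not slow_far.any():
            labels[trip.trip_id] = "nonfishing"
    return labels


# ---------------------------------------------------------------------------
# Logistic GAM
# ---------------------------------------------------------------------------

@dataclass
class GamModel:
    """Fitted penalized logistic GAM plus the feature preparation state."""

    result: object
    smoother: object
    medians: pd.Series
    factor_levels: dict
    train_ranges: dict
    threshold: float = 0.5

    def design(self, features: pd.DataFrame):
        """(exog_linear, x_smooth, extrapolation_flag) for a feature frame."""
        df = features.copy()
        if df.empty:
            raise ValueError("empty feature set")
        df["ln_duration"] = np.log(df["duration"])
        extrap = np.zeros(len(df), dtype=bool)
        for c in _SMOOTH_COLS:
            miss = ~np.isfinite(df[c].to_numpy(dtype=float))
            df.loc[miss, c] = self.medians[c]
            lo, hi = self.train_ranges[c]
            v = df[c].to_numpy(dtype=float)
            extrap |= (v < lo) | (v > hi)
            df[c] = np.clip(v, lo, hi)
        x_smooth = df[list(_SMOOTH_COLS)].to_numpy(dtype=float)
        cols = [np.ones(len(df)),
                df["ln_duration"].to_numpy() * df["avesp"].to_numpy(),
                df["avesp_missing"].to_numpy(dtype=float),
                df["sddif_missing"].to_numpy(dtype=float)]
        names = ["const", "lnd_x_avesp", "avesp_missing", "sddif_missing"]
        for c in _FACTOR_COLS:
            for lev in self.factor_levels[c][1:]:  # first level is reference
                cols.append((df[c] == lev).to_numpy(dtype=float))
                names.append(f"{c}_{lev}")
        exog = pd.DataFrame(np.column_stack(cols), columns=names,
                            index=df.index)
        return exog, x_smooth, extrap


def fit_gam(features: pd.DataFrame, labels, split: float = 0.75,
            seed: int = 0, alpha: float = 1.0,
            duration_bounds: tuple = (200.0, 15000.0)):
    """Fit the logistic GAM on labeled trips; returns (GamModel, report).

    ``labels`` is a Series/dict of 'fishing'/'nonfishing' (or 1/0) keyed
    by trip_id.  Trips outside the duration bounds are excluded from
    training/testing as unrepresentative.  The data are split into
    training and held-out fractions (default 75/25, stratified) and
    held-out accuracy and training deviance explained are reported.
    Perfect separation triggers refits at stronger penalties.
    """
    y = pd.Series(labels)
    y = y.map({"fishing": 1, "nonfishing": 0, 1: 1, 0: 0}).astype(float)
    df = features.loc[features.index.intersection(y.index)].copy()
    y = y.loc[df.index]
    lo, hi = duration_bounds
    keep = (df["duration"] > lo) & (df["duration"] < hi)
    df, y = df.loc[keep], y.loc[keep]
    if len(df) < 50:
        raise ValueError("too few labeled trips to fit the model")
    if y.nunique() < 2:
        raise ValueError("both classes must be present")
    df["ln_duration"] = np.log(df["duration"])
    medians = df[list(_SMOOTH_COLS)].median()
    factor_levels = {c: sorted(df[c].unique()) for c in _FACTOR_COLS}
    for c in _SMOOTH_COLS:
        miss = ~np.isfinite(df[c].to_numpy(dtype=float))
        df.loc[miss, c] = medians[c]
    idx_train, idx_test = train_test_split(
        np.arange(len(df)), train_size=split, random_state=seed, stratify=y)
    # clip ranges come from the training rows: the spline knots live there
    train_ranges = {c: (float(df[c].iloc[idx_train].min()),
                        float(df[c].iloc[idx_train].max()))
                    for c in _SMOOTH_COLS}
    model = GamModel(result=None, smoother=None, medians=medians,
                     factor_levels=factor_levels, train_ranges=train_ranges)
    exog, x_smooth, _ = model.design(df)
    x_tr, x_te = x_smooth[idx_train], x_smooth[idx_test]
    bs = BSplines(x_tr, df=[6] * len(_SMOOTH_COLS),
                  degree=[3] * len(_SMOOTH_COLS))
    y_tr = y.to_numpy()[idx_train]
    exog_tr = exog.iloc[idx_train]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gam = GLMGam(y_tr, exog=exog_tr, smoother=bs,
                         alpha=[alpha] * len(_SMOOTH_COLS),
                         family=sm.families.Binomial())
            res = gam.fit(maxiter=100)
    except (PerfectSeparationError, np.linalg.LinAlgError):
        # classes linearly separable in feature space: the spline
        # penalty's null space is unpenalized, so PIRLS diverges; refit
        # with a small ridge on all coefficients (warning, as the
        # probabilities saturate)
        log.warning("perfect separation; refitting with ridge-stabilized "
                    "penalized IRLS")
        res = _RidgeGamResult.fit(y_tr, exog_tr.to_numpy(dtype=float),
                                  bs, x_tr, alpha)
    model.result = res
    model.smoother = bs

    p_te = _predict_raw(model, exog.iloc[idx_test], x_te)
    acc = float(np.mean((p_te >= model.threshold)
                        == (y.to_numpy()[idx_test] == 1)))
    dev_expl = float(1.0 - res.deviance / res.null_deviance)
    report = {"n_train": len(idx_train), "n_test": len(idx_test),
              "holdout_accuracy": acc, "deviance_explained": dev_expl}
    return model, report


class _RidgeGamResult:
    """Penalized-IRLS logistic GAM fit with a ridge on every coefficient.

    Fallback engine for perfectly separable training data; keeps the same
    B-spline smooth structure and penalty matrices, adding eps*I so the
    coefficient vector stays bounded.
    """

    def __init__(self, params, bs, deviance, null_deviance):
        self.params = params
        self._bs = bs
        self.deviance = deviance
        self.null_deviance = null_deviance

    @staticmethod
    def _design(exog, bs, x_smooth):
        return np.column_stack([np.asarray(exog, dtype=float),
                                bs.transform(x_smooth)])

    @classmethod
    def fit(cls, y, exog, bs, x_smooth, alpha, ridge=1e-3, maxiter=100):
        import scipy.linalg
        X = cls._design(exog, bs, x_smooth)
        n_lin = np.asarray(exog).shape[1]
        P = scipy.linalg.block_diag(
            np.zeros((n_lin, n_lin)),
            *[alpha * m for m in bs.penalty_matrices])
        P += ridge * np.eye(X.shape[1])
        beta = np.zeros(X.shape[1])
        dev = np.inf
        for _ in range(maxiter):
            eta = X @ beta
            mu = 1.0 / (1.0 + np.exp(-eta))
            mu = np.clip(mu, 1e-10, 1 - 1e-10)
            w = mu * (1 - mu)
            z = eta + (y - mu) / w
            beta = np.linalg.solve(X.T @ (w[:, None] * X) + P,
                                   X.T @ (w * z))
            new_dev = float(-2 * np.sum(y * np.log(mu)
                                        + (1 - y) * np.log(1 - mu)))
            if abs(new_dev - dev) < 1e-6 * (abs(dev) + 1):
                break
            dev = new_dev
        p0 = np.clip(y.mean(), 1e-10, 1 - 1e-10)
        null_dev = float(-2 * np.sum(y * np.log(p0) + (1 - y) * np.log(1 - p0)))
        return cls(beta, bs, dev, null_dev)

    def predict(self, exog, exog_smooth, transform=False):
        X = self._design(exog, self._bs, exog_smooth)
        return 1.0 / (1.0 + np.exp(-(X @ self.params)))


def _predict_raw(model: GamModel, exog, x_smooth):
    return np.asarray(model.result.predict(
        exog=np.asarray(exog, dtype=float), exog_smooth=x_smooth))


def predict_fishing(model: GamModel, features: pd.DataFrame) -> pd.DataFrame:
    """Fishing probability and label per trip.

    Features outside the training range are clipped to it and flagged
    ``extrapolated``.  A probability exactly at the threshold is labeled
    fishing.
    """
    exog, x_smooth, extrap = model.design(features)
    p = _predict_raw(model, exog, x_smooth)
    return pd.DataFrame({
        "p_fishing": p,
        "label": np.where(p >= model.threshold, "fishing", "nonfishing"),
        "extrapolated": extrap,
    }, index=features.index)


def classify_trips(trips, records, ports, rule_config=None,
                   fishing_areas=None, split=0.75, seed=0):
    """Rules-then-model classification of all trips.

    Applies the decision rules, fits the GAM on the rule-labeled trips,
    predicts the remainder, and writes 'fishing'/'nonfishing' into
    ``trip.label`` (fishing trips are refined to AFA/non-AFA by
    :func:`vmstrips.ticket_matching.partition_afa`).  Returns a report
    with rule/model counts and the held-out model accuracy.
    """
    features = compute_features(trips, records, ports, fishing_areas)
    rule_labels = apply_decision_rules(trips, records, rule_config)
    unlabeled = [t for t in trips if t.trip_id not in rule_labels]
    report = {"n_rule_labeled": len(rule_labels),
              "n_model_labeled": len(unlabeled)}
    model = None
    if unlabeled:
        try:
            model, fit_report = fit_gam(features.loc[list(rule_labels)],
                                        rule_labels, split=split, seed=seed)
        except ValueError as err:
            log.warning("model not fitted (%s); %d trips left unclassified",
                        err, len(unlabeled))
            report["model_error"] = str(err)
        else:
            report.update(fit_report)
            pred = predict_fishing(model, features.loc[[t.trip_id
                                                        for t in unlabeled]])
            for t in unlabeled:
                rule_labels[t.trip_id] = str(pred.loc[t.trip_id, "label"])
    for t in trips:
        lab = rule_labels.get(t.trip_id)
        t.label = {"fishing": "fishing", "nonfishing": "nonfishing",
                   None: "unclassified"}[lab]
    report["n_classified"] = sum(t.label != "unclassified" for t in trips)
    return model, report
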