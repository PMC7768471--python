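"""Survival machinery for the TMA-style marker analysis: endpoint
derivation, Kaplan-Meier estimation, log-rank tests with BH-adjusted
pairwise comparisons, maximally-selected-rank cutpoints, and Cox
proportional-hazards regression.

Endpoints follow the study's definitions: clinical progression is
metastasis or local recurrence; disease progression combines any form of
recurrence (PSA or clinical); patients without an event are censored at the
last follow-up.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger("xenostroma")

ENDPOINTS = ("os", "clinical_progression", "psa_progression", "disease_progression")


@dataclass
class ClinicalRecord:
    patient_id: str
    cores: list[float]
    stage: str
    gleason: int
    endpoints: dict[str, tuple[float, int]] = field(default_factory=dict)

    @property
    def marker(self) -> float:
        return float(np.mean(self.cores))


# ---------------------------------------------------------------------------
# endpoints
# ---------------------------------------------------------------------------

def derive_endpoints(raw: pd.DataFrame) -> list[ClinicalRecord]:
    """Build per-patient endpoint (time, event) pairs from raw clinical rows.

    Expects columns ``psa_rec_time/_event``, ``metastasis_time/_event``,
    ``local_rec_time/_event``, ``os_time/_event``, ``last_followup``,
    ``core_*``, ``stage``, ``gleason``.  Clinical progression fires on
    metastasis or local recurrence (earliest event time); disease
    progression on PSA or clinical progression.  Rows with negative times
    are rejected with a log entry.
    """
    records = []
    time_cols = [c for c in raw.columns if c.endswith("_time")] + ["last_followup"]
    core_cols = sorted(c for c in raw.columns if c.startswith("core_"))
    for pid, row in raw.iterrows():
        if any(row[c] < 0 for c in time_cols):
            log.warning("patient %s: negative time, row rejected", pid)
            continue
        last = float(row["last_followup"])

        def combine(parts: list[tuple[float, int]]) -> tuple[float, int]:
            ev = [(t, e) for t, e in parts if e == 1]
            if ev:
                return (min(t for t, _ in ev), 1)
            return (last, 0)

        psa = (float(row["psa_rec_time"]), int(row["psa_rec_event"]))
        clin = combine([(float(row["metastasis_time"]), int(row["metastasis_event"])),
                        (float(row["local_rec_time"]), int(row["local_rec_event"]))])
        psa_ep = combine([psa])
        disease = combine([psa_ep, clin])
        os_ep = combine([(float(row["os_time"]), int(row["os_event"]))])
        records.append(ClinicalRecord(
            str(pid), [float(row[c]) for c in core_cols],
            str(row.get("stage", "")), int(row.get("gleason", 0)),
            {"os": os_ep, "clinical_progression": clin,
             "psa_progression": psa_ep, "disease_progression": disease}))
    return records


def endpoint_frame(records: list[ClinicalRecord], endpoint: str) -> pd.DataFrame:
    return pd.DataFrame(
        {"time": [r.endpoints[endpoint][0] for r in records],
         "event": [r.endpoints[endpoint][1] for r in records],
         "marker": [r.marker for r in records],
         "stage": [r.stage for r in records],
         "gleason": [r.gleason for r in records]},
        index=pd.Index([r.patient_id for r in records], name="patient_id"))


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

@dataclass
class KMCurve:
    times: np.ndarray        # event times (sorted, unique)
    survival: np.ndarray     # S(t) just after each event time
    variance: np.ndarray     # Greenwood variance of S(t)
    n: int
    n_events: int

    def at(self, t: float) -> float:
        """S(t); right-continuous step function with S(0) = 1."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_fit(times, events) -> KMCurve:
    """Product-limit estimator with Greenwood variance."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    uniq = np.unique(t[e == 1])
    surv, var_sum = [], []
    s, gw = 1.0, 0.0
    for u in uniq:
        at_risk = int((t >= u).sum())
        d = int(((t == u) & (e == 1)).sum())
        s *= 1.0 - d / at_risk
        if at_risk > d:
            gw += d / (at_risk * (at_risk - d))
        surv.append(s)
        var_sum.append(gw)
    surv = np.array(surv)
    return KMCurve(uniq, surv, surv**2 * np.array(var_sum), len(t), int(e.sum()))


def km_by_group(times, events, groups) -> dict[str, KMCurve]:
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    g = np.asarray(groups)
    return {str(lab): km_fit(t[g == lab], e[g == lab]) for lab in np.unique(g)}


# ---------------------------------------------------------------------------
# log-rank
# ---------------------------------------------------------------------------

def _logrank_oe(t: np.ndarray, e: np.ndarray, g: np.ndarray
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray, list]:
    """Observed, expected and (for 2 groups) hypergeometric variance."""
    labels = list(np.unique(g))
    k = len(labels)
    obs = np.zeros(k)
    exp = np.zeros(k)
    var = np.zeros((k, k))
    for u in np.unique(t[e == 1]):
        at = t >= u
        n = int(at.sum())
        d = int(((t == u) & (e == 1)).sum())
        for i, lab in enumerate(labels):
            ni = int((at & (g == lab)).sum())
            di = int(((t == u) & (e == 1) & (g == lab)).sum())
            obs[i] += di
            exp[i] += d * ni / n
            for j, lab2 in enumerate(labels):
                nj = int((at & (g == lab2)).sum())
                delta = 1.0 if i == j else 0.0
                if n > 1:
                    var[i, j] += d * (n - d) / (n - 1) * (ni / n) * (delta - nj / n)
    return obs, exp, var, labels


def logrank(times, events, groups) -> tuple[float, int, float]:
    """Global log-rank test; returns (chi2, df, p)."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    g = np.asarray(groups)
    if e.sum() == 0:
        raise ValueError("no events: log-rank undefined")
    obs, exp, var, labels = _logrank_oe(t, e, g)
    k = len(labels)
    if k < 2:
        raise ValueError("need at least 2 groups")
    d = (obs - exp)[:-1]
    v = var[:-1, :-1]
    try:
        chi2 = float(d @ np.linalg.solve(v, d))
    except np.linalg.LinAlgError:
        chi2 = float(d @ np.linalg.pinv(v) @ d)
    df = k - 1
    return chi2, df, float(stats.chi2.sf(chi2, df))


def logrank_z(times, events, mask: np.ndarray) -> float:
    """Standardized two-group log-rank statistic (O - E) / sqrt(V) for the
    group selected by ``mask``."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    g = np.where(np.asarray(mask), "hi", "lo")
    obs, exp, var, labels = _logrank_oe(t, e, g)
    i = labels.index("hi")
    v = var[i, i]
    if v <= 0:
        return 0.0
    return float((obs[i] - exp[i]) / np.sqrt(v))


def pairwise_logrank(times, events, groups) -> pd.DataFrame:
    """All pairwise log-rank tests with BH-adjusted p-values."""
    g = np.asarray(groups)
    labels = list(np.unique(g))
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    rows = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            sel = (g == labels[i]) | (g == labels[j])
            chi2, _, p = logrank(t[sel], e[sel], g[sel])
            rows.append((labels[i], labels[j], chi2, p))
    out = pd.DataFrame(rows, columns=["group1", "group2", "chi2", "p"])
    out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# maximally selected rank statistics
# ---------------------------------------------------------------------------

@dataclass
class CutpointResult:
    cutpoint: float
    statistic: float         # standardized log-rank statistic at the cutpoint
    p_adjusted: float
    p_naive: float
    candidates: np.ndarray
    statistics: np.ndarray
    minprop: float


def _split_z_all(t_sorted: np.ndarray, e_sorted: np.ndarray,
                 above: np.ndarray) -> np.ndarray:
    """Standardized log-rank statistic for every candidate split at once.

    ``above`` is an (n x n_candidates) boolean matrix, rows in ascending
    time order, marking membership of the high-marker group per candidate.
    """
    n, _ = above.shape
    # suffix sums over time give the high-group at-risk count at each row
    n_hi = np.cumsum(above[::-1].astype(np.int64), axis=0)[::-1]
    uniq, first = np.unique(t_sorted, return_index=True)
    d_u = np.array([((t_sorted == u) & (e_sorted == 1)).sum() for u in uniq])
    n_u = (len(t_sorted) - first).astype(float)
    keep = d_u > 0
    first, d_u, n_u = first[keep], d_u[keep].astype(float), n_u[keep]
    s = n_hi[first, :].astype(float)                 # high-group at risk per event time
    obs = above[e_sorted == 1, :].sum(axis=0).astype(float)
    exp = (d_u[:, None] * s / n_u[:, None]).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = s / n_u[:, None]
        mult = np.where(n_u > 1, d_u * (n_u - d_u) / (n_u - 1), 0.0)
        var = (mult[:, None] * frac * (1.0 - frac)).sum(axis=0)
        z = np.where(var > 0, (obs - exp) / np.sqrt(var), 0.0)
    return z


def _max_cut(t: np.ndarray, e: np.ndarray, marker: np.ndarray,
             candidates: np.ndarray) -> tuple[float, float, np.ndarray]:
    order = np.argsort(t, kind="stable")
    above = marker[order, None] > candidates[None, :]
    zs = np.abs(_split_z_all(t[order], e[order], above))
    best = int(np.argmax(zs))  # argmax takes the first (smallest cutpoint) on ties
    return float(candidates[best]), float(zs[best]), zs


def maxstat_cutpoint(times, events, marker, minprop: float = 0.1,
                     pmethod: str = "permutation", n_perm: int = 10000,
                     seed: int = 0) -> CutpointResult:
    """Optimal marker cutpoint by maximally selected rank statistics.

    Candidate cutpoints are midpoints between consecutive distinct marker
    values leaving at least ``minprop`` of the patients on each side.  The
    selected cutpoint maximizes the absolute standardized two-group log-rank
    statistic (ties go to the smaller cutpoint).  The selection-adjusted
    p-value comes from permuting the marker over patients (default) or from
    the Ornstein-Uhlenbeck bridge approximation over the candidate range.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    m = np.asarray(marker, dtype=float)
    n = len(t)
    uniq = np.unique(m)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    if len(mids) == 0:
        raise ValueError("constant marker: no admissible cutpoint")
    admissible = np.array([minprop * n <= (m > c).sum() <= (1 - minprop) * n
                           for c in mids])
    candidates = mids[admissible]
    if len(candidates) < 1:
        raise ValueError("no admissible cutpoint at this minprop")
    cut, z_max, zs = _max_cut(t, e, m, candidates)
    p_naive = 2.0 * stats.norm.sf(z_max)

    if pmethod == "permutation":
        rng = np.random.default_rng(seed)
        order = np.argsort(t, kind="stable")
        t_s, e_s = t[order], e[order]
        above0 = m[:, None] > candidates[None, :]   # original patient order
        hits = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            z_p = np.abs(_split_z_all(t_s, e_s, above0[perm][order])).max()
            if z_p >= z_max:
                hits += 1
        p_adj = (hits + 1) / (n_perm + 1)
    elif pmethod == "approx":
        # Ornstein-Uhlenbeck bridge bound over the candidate proportion range
        props = np.array([(m <= c).mean() for c in candidates])
        q1, q2 = float(props.min()), float(props.max())
        b = z_max
        if b < 1e-8:
            p_adj = 1.0
        else:
            phi = stats.norm.pdf(b)
            logterm = np.log((q2 * (1 - q1)) / ((1 - q2) * q1))
            p_adj = min(1.0, phi * (b - 1.0 / b) * logterm + 4.0 * phi / b)
    else:
        raise ValueError("pmethod must be 'permutation' or 'approx'")
    p_adj = max(p_adj, p_naive)  # selection can only cost, never gain
    return CutpointResult(cut, z_max, float(min(p_adj, 1.0)), float(p_naive),
                          candidates, zs, minprop)


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------

@dataclass
class CoxResult:
    beta: np.ndarray
    hr: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    p: np.ndarray
    se: np.ndarray
    score_chi2: float
    loglik: float
    converged: bool
    names: list[str]

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({"beta": self.beta, "HR": self.hr,
                             "ci_lower": self.ci_lower, "ci_upper": self.ci_upper,
                             "p": self.p, "se": self.se}, index=self.names)


def _cox_loglik(beta, t, e, x, ties="breslow"):
    """Breslow/Efron partial log-likelihood with gradient and Hessian."""
    eta = x @ beta
    w = np.exp(eta)
    order = np.argsort(-t, kind="stable")   # decreasing time
    t_s, e_s, x_s, w_s = t[order], e[order], x[order], w[order]
    n, p = x.shape
    ll, grad, hess = 0.0, np.zeros(p), np.zeros((p, p))
    s0, s1, s2 = 0.0, np.zeros(p), np.zeros((p, p))
    i = 0
    while i < n:
        j = i
        while j < n and t_s[j] == t_s[i]:
            j += 1
        for kk in range(i, j):       # extend risk set by this tie block
            s0 += w_s[kk]
            s1 += w_s[kk] * x_s[kk]
            s2 += w_s[kk] * np.outer(x_s[kk], x_s[kk])
        dead = [kk for kk in range(i, j) if e_s[kk] == 1]
        d = len(dead)
        if d:
            xd = x_s[dead].sum(axis=0)
            if ties == "breslow":
                ll += eta[order][dead].sum() - d * np.log(s0)
                grad += xd - d * s1 / s0
                hess -= d * (s2 / s0 - np.outer(s1, s1) / s0**2)
            else:                    # efron
                wd = w_s[dead].sum()
                w1 = (w_s[dead][:, None] * x_s[dead]).sum(axis=0)
                w2 = sum(w_s[kk] * np.outer(x_s[kk], x_s[kk]) for kk in dead)
                ll += eta[order][dead].sum()
                for r in range(d):
                    f = r / d
                    den = s0 - f * wd
                    num1 = s1 - f * w1
                    num2 = s2 - f * w2
                    ll -= np.log(den)
                    grad -= num1 / den
                    hess -= num2 / den - np.outer(num1, num1) / den**2
                grad += xd
        i = j
    return ll, grad, hess


def cox_fit(times, events, covariates, ties: str = "breslow",
            max_iter: int = 50, tol: float = 1e-8, beta_cap: float = 15.0) -> CoxResult:
    """Cox regression by Newton-Raphson with step-halving.

    Monotone likelihood (complete separation) is flagged and the coefficient
    capped with a warning rather than diverging.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    x = np.asarray(covariates, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    names = (list(covariates.columns) if isinstance(covariates, pd.DataFrame)
             else [f"x{i + 1}" for i in range(x.shape[1])])
    if e.sum() < 1:
        raise ValueError("need at least one event")
    sds = x.std(axis=0)
    if (sds == 0).any():
        raise ValueError("constant covariate")

    beta = np.zeros(x.shape[1])
    ll, grad, hess = _cox_loglik(beta, t, e, x, ties)
    score_chi2 = float(grad @ np.linalg.solve(-hess, grad))
    converged = False
    for _ in range(max_iter):
        step = np.linalg.solve(-hess, grad)
        new_beta = beta + step
        new_ll, new_grad, new_hess = _cox_loglik(new_beta, t, e, x, ties)
        halvings = 0
        while new_ll < ll and halvings < 20:   # step-halving keeps ll monotone
            step /= 2.0
            new_beta = beta + step
            new_ll, new_grad, new_hess = _cox_loglik(new_beta, t, e, x, ties)
            halvings += 1
        beta, ll, grad, hess = new_beta, new_ll, new_grad, new_hess
        if np.abs(step).max() < tol:
            converged = True
            break
    capped = np.abs(beta * sds) > beta_cap
    if capped.any():
        log.warning("cox_fit: monotone likelihood suspected; capping %s",
                    [names[i] for i in np.nonzero(capped)[0]])
        beta = np.clip(beta, -beta_cap / sds, beta_cap / sds)
        ll, grad, hess = _cox_loglik(beta, t, e, x, ties)
        converged = False
    se = np.sqrt(np.diag(np.linalg.inv(-hess)))
    z = beta / se
    ci = 1.959963984540054 * se
    with np.errstate(over="ignore"):
        return CoxResult(beta, np.exp(beta), np.exp(beta - ci), np.exp(beta + ci),
                         2.0 * stats.norm.sf(np.abs(z)), se, score_chi2, float(ll),
                         converged, names)
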