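"""Synthetic dyad generator.

Produces data with the statistical structure the analysis assumes so every
pipeline stage is testable without any external download:

* respiratory-band-modulated IBI series whose per-second log-amplitude
  envelopes follow AR(1) with innovations cross-correlated within dyads at a
  controllable level (coupling planted in envelope *increments*, matching the
  first-differenced synchrony definition downstream);
* coupled Markov affect streams with a controllable shared-positive boost and
  i.i.d. uncodable injection;
* sparse unsupportive-ERSB streams with a planted any-use rate;
* dyad-level outcomes from a linear model with synchrony-by-parent-factor
  interaction terms and stored ground-truth coefficients.

All randomness flows through an explicit ``numpy.random.Generator``; no
global state.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as dio
from .types import AFFECT_CODES, UNCODABLE, CodedStream, IBISeries

AFFECT_STATES = list(AFFECT_CODES)  # positive_warm, dysphoric, angry_aggressive, neutral


@dataclass
class OutcomeModel:
    """Linear data-generating model for the child symptom T-score."""

    intercept: float = 57.60            # child dep T mean
    b_parent_dep: float = 0.18
    b_ersb_any: float = 1.22
    b_affect_sync: float = -2.83
    b_rsa_sync: float = 0.0
    b_int_affect_ersb: float = 8.45     # affect synchrony x unsupportive ERSB
    b_int_rsa_parent_dep: float = -2.37 # RSA synchrony x parent depression
    b_child_medication: float = 0.0
    b_pubertal_status: float = 0.0
    b_pandemic_cohort: float = 0.0
    resid_sd: float = 5.0


@dataclass
class SimConfig:
    """All knobs of the synthetic study."""

    n_dyads: int = 80
    task_s: int = 300

    # cardiac / respiratory structure
    base_ibi_ms: dict = field(default_factory=lambda: {"parent": 850.0, "child": 700.0})
    resp_freq_hz: dict = field(default_factory=lambda: {"parent": 0.25, "child": 0.30})
    env_level_ms: dict = field(default_factory=lambda: {"parent": 40.0, "child": 40.0})
    env_ar: float = 0.95                # AR(1) coefficient of the log-amplitude envelope
    env_innov_sd: float = 0.10
    ibi_noise_ms: float = 1.0
    rsa_change_coupling: float = 0.3    # rho of envelope innovations across members

    # affect structure
    affect_stationary: dict = field(default_factory=lambda: {
        "positive_warm": 0.05, "dysphoric": 0.03, "angry_aggressive": 0.02,
        "neutral": 0.90,
    })
    affect_persistence: float = 0.85
    shared_positive_boost: float = 5.1  # calibrated: ~54.5% of dyads show any shared positive
    uncodable_rate: float = 0.05

    # ERSB structure
    p_unsupportive_any: float = 0.425
    unsupportive_extra_seconds: float = 2.0  # given any: 1 + Poisson(this) seconds

    # covariate / predictor marginals
    parent_dep_mean: float = 55.54
    parent_dep_sd: float = 7.64
    rsa_sync_mean: float = 0.02
    rsa_sync_sd: float = 0.21
    p_affect_sync_any: float = 0.545
    p_child_medication: float = 0.30
    p_pubertal: float = 0.50
    p_pandemic: float = 0.50

    outcome: OutcomeModel = field(default_factory=OutcomeModel)

    def validate(self) -> None:
        if not -1 < self.rsa_change_coupling < 1:
            raise ValueError("rsa_change_coupling must be in (-1, 1)")
        if not 0 <= self.env_ar < 1:
            raise ValueError("env_ar must be in [0, 1)")
        if self.outcome.resid_sd < 0:
            raise ValueError("resid_sd must be >= 0")
        probs = np.array(list(self.affect_stationary.values()))
        if abs(probs.sum() - 1) > 1e-9 or np.any(probs < 0):
            raise ValueError("affect_stationary must be a probability vector")


def _envelope_pair(cfg: SimConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Per-second AR(1) log-amplitude envelopes, innovations correlated at
    rho across members (stationary init with the same cross-correlation)."""
    n = cfg.task_s
    rho = cfg.rsa_change_coupling
    phi = cfg.env_ar
    sd = cfg.env_innov_sd
    cov = np.array([[1.0, rho], [rho, 1.0]])
    chol = np.linalg.cholesky(cov)
    innov = rng.standard_normal((n, 2)) @ chol.T * sd
    e = np.empty((n, 2))
    e[0] = innov[0] / np.sqrt(1 - phi**2)
    for t in range(1, n):
        e[t] = phi * e[t - 1] + innov[t]
    return e[:, 0], e[:, 1]


def _emit_beats(
    cfg: SimConfig, role: str, envelope: np.ndarray, rng: np.random.Generator,
) -> IBISeries:
    """Integrate instantaneous IBI to beat times (inverse cumulative method)
    so the respiratory modulation survives the spline-resampling stage."""
    base = cfg.base_ibi_ms[role]
    level = cfg.env_level_ms[role]
    freq = cfg.resp_freq_hz[role]
    sec_centers = np.arange(cfg.task_s) + 0.5

    times: list[float] = []
    intervals: list[float] = []
    t = 0.0
    while t < cfg.task_s:
        amp = level * np.exp(np.interp(t, sec_centers, envelope))
        ibi = base + amp * np.sin(2 * np.pi * freq * t)
        ibi += rng.normal(0.0, cfg.ibi_noise_ms)
        ibi = max(ibi, 250.0)
        t += ibi / 1000.0
        times.append(t)
        intervals.append(ibi)
    return IBISeries(
        person_id=f"{role}", beat_times=np.array(times), intervals=np.array(intervals),
    )


def gen_ibi_dyad(
    cfg: SimConfig, rng: np.random.Generator, dyad_id: str = "d0",
) -> tuple[IBISeries, IBISeries, dict]:
    """One dyad's parent/child IBI series plus the ground-truth coupling
    record (realized per-second envelopes and the planted rho)."""
    cfg.validate()
    env_p, env_c = _envelope_pair(cfg, rng)
    parent = _emit_beats(cfg, "parent", env_p, rng)
    child = _emit_beats(cfg, "child", env_c, rng)
    parent.person_id = f"{dyad_id}_parent"
    child.person_id = f"{dyad_id}_child"
    truth = {
        "dyad_id": dyad_id,
        "rho": cfg.rsa_change_coupling,
        "envelope_parent": env_p,
        "envelope_child": env_c,
    }
    return parent, child, truth


def envelope_oracle_z(truth: dict, second_weights: np.ndarray | None = None) -> float:
    """Fisher z of the correlation between first-differenced true envelopes —
    the ground-truth value the pipeline estimate is compared against.

    Without ``second_weights`` the raw per-second envelope increments are
    correlated. With ``second_weights`` (the estimator's per-second window
    energy profile, see :func:`dyadsync.rsa.taper_second_weights`) the oracle
    is the same estimand the short-time estimator targets: ln of the
    window-weighted mean instantaneous power exp(2e), first-differenced.
    """
    ep = truth["envelope_parent"]
    ec = truth["envelope_child"]
    if second_weights is not None:
        k = np.asarray(second_weights)[::-1]
        ep = np.log(np.convolve(np.exp(2 * ep), k, mode="valid"))
        ec = np.log(np.convolve(np.exp(2 * ec), k, mode="valid"))
    r = float(np.corrcoef(np.diff(ep), np.diff(ec))[0, 1])
    return float(np.arctanh(r))


def _transition_matrix(cfg: SimConfig) -> np.ndarray:
    """Sticky chain with the configured stationary distribution:
    T = s*I + (1-s)*1'pi."""
    pi = np.array([cfg.affect_stationary[s] for s in AFFECT_STATES])
    s = cfg.affect_persistence
    return s * np.eye(len(pi)) + (1 - s) * np.tile(pi, (len(pi), 1))


def gen_affect_dyad(
    cfg: SimConfig, rng: np.random.Generator, dyad_id: str = "d0",
) -> tuple[CodedStream, CodedStream]:
    """Coupled Markov affect chains: while the partner is in positive_warm,
    transition probability into positive_warm is multiplied by the boost and
    the row renormalized. Uncodable seconds are injected i.i.d."""
    cfg.validate()
    T = _transition_matrix(cfg)
    pi = np.array([cfg.affect_stationary[s] for s in AFFECT_STATES])
    pos = AFFECT_STATES.index("positive_warm")
    n = cfg.task_s

    states = np.empty((n, 2), dtype=int)
    states[0, 0] = rng.choice(len(pi), p=pi)
    states[0, 1] = rng.choice(len(pi), p=pi)
    for t in range(1, n):
        for member in (0, 1):
            row = T[states[t - 1, member]].copy()
            partner_prev = states[t - 1, 1 - member]
            if partner_prev == pos and cfg.shared_positive_boost != 1.0:
                row[pos] = min(row[pos] * cfg.shared_positive_boost, 0.95)
                row /= row.sum()
            states[t, member] = rng.choice(len(pi), p=row)

    def _stream(col: int, role: str) -> CodedStream:
        codes = np.array([AFFECT_STATES[s] for s in states[:, col]], dtype=object)
        unc = rng.random(n) < cfg.uncodable_rate
        codes[unc] = UNCODABLE
        return CodedStream(
            person_id=f"{dyad_id}_{role}", role=role, stream_kind="affect", codes=codes,
        )

    return _stream(0, "parent"), _stream(1, "child")


def gen_ersb_stream(
    cfg: SimConfig, rng: np.random.Generator, dyad_id: str = "d0",
) -> CodedStream:
    """Sparse unsupportive-ERSB stream: with probability p_unsupportive_any
    the parent shows 1 + Poisson(k) unsupportive seconds; the rest of the
    task is supportive/none."""
    n = cfg.task_s
    codes = np.array(
        rng.choice(["none", "supportive"], size=n, p=[0.8, 0.2]), dtype=object,
    )
    if rng.random() < cfg.p_unsupportive_any:
        n_unsup = 1 + rng.poisson(cfg.unsupportive_extra_seconds)
        n_unsup = min(n_unsup, n)
        where = rng.choice(n, size=n_unsup, replace=False)
        kinds = rng.choice(["dismissing", "mild_rejection", "firm_rejection"],
                           size=n_unsup, p=[0.6, 0.3, 0.1])
        codes[where] = kinds
    unc = rng.random(n) < cfg.uncodable_rate
    codes[unc] = UNCODABLE
    return CodedStream(
        person_id=f"{dyad_id}_parent_ersb", role="parent", stream_kind="ersb",
        codes=codes,
    )


def gen_outcome_table(
    cfg: SimConfig, summaries: pd.DataFrame, rng: np.random.Generator,
) -> tuple[pd.DataFrame, dict]:
    """Attach covariates, parent symptoms, and a model-generated child
    symptom T-score to per-dyad summaries.

    ``summaries`` needs columns dyad_id, shared_positive_any,
    unsupportive_any, rsa_z. Continuous predictors enter centered at their
    configured population means; ground-truth coefficients are returned
    alongside the table.
    """
    df = summaries.copy()
    n = len(df)
    om = cfg.outcome

    df["parent_dep_T"] = np.maximum(
        rng.normal(cfg.parent_dep_mean, cfg.parent_dep_sd, size=n), 0.0)
    df["child_medication"] = rng.binomial(1, cfg.p_child_medication, size=n)
    df["pubertal_status"] = rng.binomial(1, cfg.p_pubertal, size=n)
    df["pandemic_cohort"] = rng.binomial(1, cfg.p_pandemic, size=n)

    pd_c = df["parent_dep_T"] - cfg.parent_dep_mean
    rsa_c = df["rsa_z"] - cfg.rsa_sync_mean
    affect = df["shared_positive_any"].astype(float)
    ersb = df["unsupportive_any"].astype(float)

    mu = (
        om.intercept
        + om.b_parent_dep * pd_c
        + om.b_ersb_any * ersb
        + om.b_affect_sync * affect
        + om.b_rsa_sync * rsa_c
        + om.b_int_affect_ersb * affect * ersb
        + om.b_int_rsa_parent_dep * rsa_c * pd_c
        + om.b_child_medication * df["child_medication"]
        + om.b_pubertal_status * df["pubertal_status"]
        + om.b_pandemic_cohort * df["pandemic_cohort"]
    )
    df["child_dep_T"] = np.maximum(mu + rng.normal(0, om.resid_sd, size=n), 0.0)

    truth = {"outcome_model": asdict(om),
             "centering": {"parent_dep_T": cfg.parent_dep_mean,
                           "rsa_z": cfg.rsa_sync_mean}}
    return df, truth


def gen_analysis_table(
    cfg: SimConfig, n: int, rng: np.random.Generator,
) -> tuple[pd.DataFrame, dict]:
    """Dyad-level analysis table drawn directly from the configured
    marginals (no physiological simulation) — for moderation-model studies
    where only the regression layer is exercised."""
    summaries = pd.DataFrame({
        "dyad_id": [f"d{i:04d}" for i in range(n)],
        "shared_positive_any": rng.binomial(1, cfg.p_affect_sync_any, size=n),
        "unsupportive_any": rng.binomial(1, cfg.p_unsupportive_any, size=n),
        "rsa_z": rng.normal(cfg.rsa_sync_mean, cfg.rsa_sync_sd, size=n),
    })
    return gen_outcome_table(cfg, summaries, rng)


@dataclass
class SimulatedDyad:
    dyad_id: str
    parent_ibi: IBISeries
    child_ibi: IBISeries
    parent_affect: CodedStream
    child_affect: CodedStream
    parent_ersb: CodedStream
    truth: dict


def simulate_study(cfg: SimConfig, rng: np.random.Generator) -> list[SimulatedDyad]:
    """Full in-memory study: physiological + behavioral streams per dyad."""
    cfg.validate()
    dyads = []
    for i in range(cfg.n_dyads):
        dyad_id = f"d{i:04d}"
        p_ibi, c_ibi, truth = gen_ibi_dyad(cfg, rng, dyad_id)
        p_aff, c_aff = gen_affect_dyad(cfg, rng, dyad_id)
        ersb = gen_ersb_stream(cfg, rng, dyad_id)
        dyads.append(SimulatedDyad(dyad_id, p_ibi, c_ibi, p_aff, c_aff, ersb, truth))
    return dyads


def write_study(
    dyads: list[SimulatedDyad],
    outcome_table: pd.DataFrame,
    outdir,
    truth: dict | None = None,
) -> None:
    """Write the study in exactly the formats ``dyadsync.io`` consumes:
    per-dyad CSVs, a manifest, the covariate/outcome table, and
    ground_truth.json."""
    outdir = Path(outdir)
    data = outdir / "data"
    data.mkdir(parents=True, exist_ok=True)

    manifest_rows = []
    gt = {"dyads": {}, "study": truth or {}}
    for d in dyads:
        row = {"dyad_id": d.dyad_id}
        for attr, suffix, writer in (
            ("parent_ibi", "parent_ibi", dio.write_ibi),
            ("child_ibi", "child_ibi", dio.write_ibi),
            ("parent_affect", "parent_affect", dio.write_coded_stream),
            ("child_affect", "child_affect", dio.write_coded_stream),
            ("parent_ersb", "parent_ersb", dio.write_coded_stream),
        ):
            obj = getattr(d, attr)
            fname = f"{d.dyad_id}_{suffix}.csv"
            writer(obj, data / fname)
            row[suffix] = fname
        manifest_rows.append(row)
        gt["dyads"][d.dyad_id] = {
            "rho": d.truth["rho"],
            "oracle_z": envelope_oracle_z(d.truth),
        }
    pd.DataFrame(manifest_rows).to_csv(data / "manifest.csv", index=False)

    outcome_table.to_csv(data / "outcomes.csv", index=False)
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(gt, fh, indent=2)
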