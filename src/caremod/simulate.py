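"""Synthetic data generators with known ground truth.

Three generators emulate the experiments of a four-condition
(NCM460/HT29 x control/DFMO) polyamine-inhibition study:

* :func:`simulate_calcium` -- single-cell fura-2 ratio traces with a
  hierarchical design (day and coverslip random intercepts) and a
  three-phase template: flat baseline, CPA-induced Ca2+ release in
  Ca2+-free medium (difference-of-exponentials pulse), and a
  saturating SOCE plateau after Ca2+ re-addition, sampled every 5 s.
* :func:`simulate_expression_pair` -- two gene x sample log2-expression
  matrices sharing one factorial truth (line, treatment, line x
  treatment interaction, day block), the second platform being a
  gain/offset-distorted, independently noisy view of the first
  platform's noiseless truth.
* :func:`simulate_qpcr` -- triplicate Ct tables under the exponential
  amplification model ``Ct = baseline - log2(abundance) + noise`` with
  a constant-abundance housekeeping gene.

Each generator returns its ground truth alongside the data so recovery
can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import Protocol
from .panel import load_panel

LINES = ("NCM460", "HT29")
TREATMENTS = ("control", "DFMO")
#: canonical condition order: line-major
CONDITIONS = tuple(f"{ln}:{tr}" for ln in LINES for tr in TREATMENTS)


def condition_label(line: str, treatment: str) -> str:
    return f"{line}:{treatment}"


# ---------------------------------------------------------------------------
# calcium traces
# ---------------------------------------------------------------------------

#: default condition means (resting ratio, release amplitude, SOCE amplitude).
#: Cancer cells rest higher, hold less releasable Ca2+ and show larger SOCE;
#: DFMO shifts the cancer line toward the normal phenotype while barely
#: affecting normal cells.
DEFAULT_CONDITION_MEANS = {
    "NCM460:control": (0.40, 0.60, 0.50),
    "NCM460:DFMO": (0.38, 0.55, 0.50),
    "HT29:control": (0.50, 0.35, 0.90),
    "HT29:DFMO": (0.42, 0.55, 0.60),
}


@dataclass
class CalciumSimConfig:
    """Configuration of the calcium-trace simulator.

    The default design mirrors a 4-day experiment with 2 coverslips per
    condition and day (8 coverslips per condition) and ~32 cells per
    coverslip, i.e. roughly 250 cells per condition, in the range of the
    per-condition counts of typical imaging campaigns (about 220-300).
    """

    n_days: int = 4
    coverslips_per_condition_day: int = 2
    cells_per_coverslip: int = 32
    sample_interval: float = 5.0
    phase_times: tuple[float, float, float] = (180.0, 600.0, 960.0)
    condition_means: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CONDITION_MEANS)
    )
    sigma_day: float = 0.02
    sigma_coverslip: float = 0.02
    sigma_cell: float = 0.05
    sigma_noise: float = 0.02
    release_rise_tau: float = 10.0
    release_decay_tau: float = 60.0
    soce_tau: float = 20.0
    seed: int = 0

    def validate(self) -> None:
        t_b, t_r, t_end = self.phase_times
        if not (0 < t_b < t_r < t_end):
            raise ValueError("phase_times must be strictly increasing and positive")
        for name in ("sigma_day", "sigma_coverslip", "sigma_cell", "sigma_noise"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if set(self.condition_means) != set(CONDITIONS):
            raise ValueError(f"condition_means must cover exactly {CONDITIONS}")
        if min(self.n_days, self.coverslips_per_condition_day, self.cells_per_coverslip) < 1:
            raise ValueError("design counts must be >= 1")
        if self.sample_interval <= 0:
            raise ValueError("sample_interval must be positive")

    def protocol(self) -> Protocol:
        t_b, t_r, t_end = self.phase_times
        return Protocol(baseline_end=t_b, readdition_start=t_r, recording_end=t_end)


def _release_template(t: np.ndarray, t_b: float, tau_rise: float, tau_decay: float) -> np.ndarray:
    """Difference-of-exponentials pulse starting at t_b, zero before."""
    dt = np.clip(t - t_b, 0.0, None)
    pulse = np.exp(-dt / tau_decay) - np.exp(-dt / tau_rise)
    pulse[t < t_b] = 0.0
    return pulse


def _soce_template(t: np.ndarray, t_r: float, tau: float) -> np.ndarray:
    """Saturating plateau starting at re-addition, zero before."""
    dt = np.clip(t - t_r, 0.0, None)
    plateau = 1.0 - np.exp(-dt / tau)
    plateau[t < t_r] = 0.0
    return plateau


def trace_template(
    times: np.ndarray, config: CalciumSimConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Unit-amplitude release and SOCE template shapes on the sample grid.

    Each template is normalised so its maximum over the sampled points of
    its own protocol window is exactly 1; the configured amplitudes are
    therefore attained exactly at a sampled time point.
    """
    t_b, t_r, t_end = config.phase_times
    release = _release_template(times, t_b, config.release_rise_tau, config.release_decay_tau)
    release[times >= t_r] = 0.0  # transient is confined to the Ca2+-free window
    soce = _soce_template(times, t_r, config.soce_tau)
    rel_win = (times >= t_b) & (times < t_r)
    soce_win = (times >= t_r) & (times < t_end)
    rel_peak = release[rel_win].max() if rel_win.any() else 1.0
    soce_peak = soce[soce_win].max() if soce_win.any() else 1.0
    return release / rel_peak, soce / soce_peak


def simulate_calcium(config: CalciumSimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a long-format trace table and its condition-level truth.

    Returns
    -------
    traces : DataFrame with columns cell_id, day, coverslip, line,
        treatment, time_s, ratio (one row per sample).
    truth : DataFrame indexed by condition with the true resting level,
        release amplitude and SOCE amplitude.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    t_end = config.phase_times[2]
    times = np.arange(0.0, t_end, config.sample_interval)
    release_u, soce_u = trace_template(times, config)

    day_labels = [f"d{i + 1}" for i in range(config.n_days)]
    day_effects = {d: rng.normal(0.0, config.sigma_day) for d in day_labels}

    frames = []
    for day in day_labels:
        for cond in CONDITIONS:
            line, treatment = cond.split(":")
            r0, d_store, d_soce = config.condition_means[cond]
            for slip_idx in range(config.coverslips_per_condition_day):
                coverslip = f"{day}_{cond}_c{slip_idx + 1}"
                slip_effect = rng.normal(0.0, config.sigma_coverslip)
                n_cells = config.cells_per_coverslip
                cell_effects = rng.normal(0.0, config.sigma_cell, size=n_cells)
                noise = rng.normal(0.0, config.sigma_noise, size=(n_cells, times.size))
                base = r0 + day_effects[day] + slip_effect
                template = d_store * release_u + d_soce * soce_u
                ratios = base + cell_effects[:, None] + template[None, :] + noise
                for ci in range(n_cells):
                    frames.append(
                        pd.DataFrame(
                            {
                                "cell_id": f"{coverslip}_cell{ci + 1:03d}",
                                "day": day,
                                "coverslip": coverslip,
                                "line": line,
                                "treatment": treatment,
                                "time_s": times,
                                "ratio": ratios[ci],
                            }
                        )
                    )
    traces = pd.concat(frames, ignore_index=True)
    truth = pd.DataFrame(
        [
            {
                "condition": cond,
                "line": cond.split(":")[0],
                "treatment": cond.split(":")[1],
                "resting": config.condition_means[cond][0],
                "store_amplitude": config.condition_means[cond][1],
                "soce_amplitude": config.condition_means[cond][2],
            }
            for cond in CONDITIONS
        ]
    ).set_index("condition")
    return traces, truth


@dataclass
class FeatureSimConfig:
    """Direct simulator of per-cell feature values (no traces).

    Generates one response per cell from the hierarchical model

        y = mean(condition) + u_day + u_coverslip + eps_cell

    with the same day/coverslip design as the trace simulator.  Used
    for Monte-Carlo studies of the condition model, where trace-level
    nuisances (peak-picking noise bias) would blur the ground truth.
    """

    n_days: int = 4
    coverslips_per_condition_day: int = 2
    cells_per_coverslip: int = 32
    condition_means: dict[str, float] = field(
        default_factory=lambda: {c: v[2] for c, v in DEFAULT_CONDITION_MEANS.items()}
    )
    sigma_day: float = 0.02
    sigma_coverslip: float = 0.02
    sigma_cell: float = 0.06
    response: str = "soce_dmax"
    seed: int = 0

    def validate(self) -> None:
        if set(self.condition_means) != set(CONDITIONS):
            raise ValueError(f"condition_means must cover exactly {CONDITIONS}")
        for name in ("sigma_day", "sigma_coverslip", "sigma_cell"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def simulate_features(config: FeatureSimConfig) -> tuple[pd.DataFrame, pd.Series]:
    """Generate a feature table and the true condition means."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    rows = []
    for d in range(config.n_days):
        day = f"d{d + 1}"
        u_day = rng.normal(0.0, config.sigma_day)
        for cond in CONDITIONS:
            line, treatment = cond.split(":")
            for s in range(config.coverslips_per_condition_day):
                coverslip = f"{day}_{cond}_c{s + 1}"
                u_cov = rng.normal(0.0, config.sigma_coverslip)
                eps = rng.normal(0.0, config.sigma_cell, size=config.cells_per_coverslip)
                y = config.condition_means[cond] + u_day + u_cov + eps
                for ci, val in enumerate(y):
                    rows.append(
                        {
                            "cell_id": f"{coverslip}_cell{ci + 1:03d}",
                            "day": day,
                            "coverslip": coverslip,
                            "line": line,
                            "treatment": treatment,
                            config.response: val,
                        }
                    )
    frame = pd.DataFrame(rows)
    truth = pd.Series(
        {c: config.condition_means[c] for c in CONDITIONS}, name=config.response
    )
    return frame, truth


# ---------------------------------------------------------------------------
# paired-platform expression
# ---------------------------------------------------------------------------


@dataclass
class ExprSimConfig:
    """Configuration of the paired-platform expression simulator.

    Truth model per gene g and sample s (log2 scale)::

        y_gs = mu_g + a_g * line_s + b_g * treat_s + c_g * line_s * treat_s
               + day_(s) + eps_gs

    with line/treat coded 0/1 (HT29 = 1, DFMO = 1).  ``a_g`` is the
    cancer (line) effect in control cells, ``b_g`` the treatment effect
    in the normal line, ``c_g`` the line x treatment interaction; the
    treatment effect in the cancer line is ``b_g + c_g``.  Platform B is
    ``gain * truth + offset`` plus independent noise.

    The default truth plants 17 treatment-affected genes within the
    Ca2+-transport panel, 11 of them sign-reversals of their cancer
    effect, plus background cancer- and treatment-affected genes among
    the non-panel genes; the normal line is left untouched by treatment,
    mimicking a treatment highly selective for cancer cells.
    """

    n_genes: int = 2000
    n_samples_per_condition: int = 4  # one per day
    effect_size: float = 1.5
    fraction_de_line: float = 0.25
    fraction_de_treatment: float = 0.15
    sigma_noise: float = 0.3
    sigma_day: float = 0.2
    baseline_mean: float = 7.0
    baseline_sd: float = 1.5
    platform2_gain: float = 1.1
    platform2_offset: float = 0.3
    platform2_sigma: float = 0.35
    use_panel: bool = True
    seed: int = 0

    def validate(self) -> None:
        if not (0 <= self.fraction_de_line <= 1 and 0 <= self.fraction_de_treatment <= 1):
            raise ValueError("DE fractions must lie in [0, 1]")
        if self.n_genes < 1 or self.n_samples_per_condition < 1:
            raise ValueError("sizes must be >= 1")
        if min(self.sigma_noise, self.sigma_day, self.platform2_sigma) < 0:
            raise ValueError("noise SDs must be >= 0")


#: panel genes whose cancer effect is reversed by treatment in the
#: cancer line: (gene, sign of cancer effect); treatment effect in the
#: cancer line takes the opposite sign.
DEFAULT_REVERSAL_PLAN = [
    ("CRACR2A", -1),
    ("ORMDL3", -1),
    ("SEPTIN6", -1),
    ("SEPTIN7", -1),
    ("SEPTIN8", -1),
    ("SEPTIN11", -1),
    ("TRPC5", +1),
    ("TRPV6", +1),
    ("SPCA2", +1),
    ("PMCA4", -1),
    ("VDAC3", -1),
]

#: panel genes affected by treatment in the cancer line but NOT reversed:
#: (gene, cancer-effect sign or 0, treatment-effect sign in cancer line).
DEFAULT_NONREVERSED_PLAN = [
    ("STIM1", +1, +1),
    ("STIM2", +1, +1),
    ("SEPTIN9", +1, +1),
    ("MCU", +1, +1),
    ("TRPC1", 0, -1),
    ("TRPP2", 0, +1),
]

#: panel genes with a cancer effect only (sign), untouched by treatment.
DEFAULT_CANCER_ONLY_PLAN = [
    ("CAV1.2", -1),
    ("CAV1.3", +1),
    ("ORAI1", -1),
    ("MBP", +1),
    ("SEPTIN3", -1),
    ("SEPTIN10", +1),
    ("SARAF", -1),
    ("TRPM2", -1),
    ("TRPML1", -1),
    ("TRPV1", -1),
    ("IP3R1", +1),
    ("IP3R2", -1),
    ("RYR2", -1),
    ("PMCA1", +1),
    ("SPCA1", -1),
    ("NCX2", +1),
    ("MICU2", -1),
    ("VDAC1", -1),
]


def _plan_truth(config: ExprSimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Build the per-gene truth table (coefficients + status)."""
    if config.use_panel:
        panel = load_panel()
        panel_genes = panel["gene"].tolist()
    else:
        panel_genes = []
    n_bg = config.n_genes - len(panel_genes)
    if n_bg < 0:
        raise ValueError("n_genes smaller than the panel size")
    genes = panel_genes + [f"G{i + 1:05d}" for i in range(n_bg)]

    truth = pd.DataFrame(
        {
            "gene": genes,
            "mu": rng.normal(config.baseline_mean, config.baseline_sd, size=len(genes)),
            "a": 0.0,  # line (cancer) effect
            "b": 0.0,  # treatment effect in the normal line
            "c": 0.0,  # line x treatment interaction
        }
    ).set_index("gene")

    eff = config.effect_size
    if config.use_panel:
        for gene, sign in DEFAULT_REVERSAL_PLAN:
            truth.loc[gene, "a"] = sign * eff
            truth.loc[gene, "c"] = -sign * eff
        for gene, a_sign, t_sign in DEFAULT_NONREVERSED_PLAN:
            truth.loc[gene, "a"] = a_sign * eff
            truth.loc[gene, "c"] = t_sign * eff
        for gene, sign in DEFAULT_CANCER_ONLY_PLAN:
            truth.loc[gene, "a"] = sign * eff

    # background genes: independent cancer and cancer-line-treatment effects
    bg = np.array([g for g in genes if g.startswith("G")])
    n_line = int(round(config.fraction_de_line * bg.size))
    n_treat = int(round(config.fraction_de_treatment * bg.size))
    line_hits = rng.choice(bg, size=n_line, replace=False)
    treat_hits = rng.choice(bg, size=n_treat, replace=False)
    truth.loc[line_hits, "a"] = rng.choice([-eff, eff], size=n_line)
    truth.loc[treat_hits, "c"] = rng.choice([-eff, eff], size=n_treat)

    treat_cancer = truth["b"] + truth["c"]
    reversed_flag = (truth["a"] != 0) & (treat_cancer != 0) & (
        np.sign(truth["a"]) == -np.sign(treat_cancer)
    )
    status = np.select(
        [
            reversed_flag,
            (truth["a"] != 0) & (treat_cancer != 0),
            truth["a"] != 0,
            treat_cancer != 0,
        ],
        ["reversed", "DE_both", "DE_cancer", "DE_treatment"],
        default="null",
    )
    truth["status"] = status
    truth["is_panel"] = [not g.startswith("G") for g in truth.index]
    return truth


def simulate_expression_pair(
    config: ExprSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate paired-platform log2 expression matrices with shared truth.

    Returns
    -------
    matrix_a, matrix_b : gene x sample DataFrames (log2 scale).
    sheet : sample sheet with sample_id, line, treatment, day (days
        balanced across conditions, one replicate per condition per day).
    truth : per-gene truth table (mu, a, b, c, status, is_panel).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    truth = _plan_truth(config, rng)

    n_rep = config.n_samples_per_condition
    rows = []
    for day_idx in range(n_rep):
        for line_code, line in enumerate(LINES):
            for treat_code, treatment in enumerate(TREATMENTS):
                rows.append(
                    {
                        "sample_id": f"{line}_{treatment}_d{day_idx + 1}",
                        "line": line,
                        "treatment": treatment,
                        "day": f"d{day_idx + 1}",
                        "_line": line_code,
                        "_treat": treat_code,
                    }
                )
    sheet = pd.DataFrame(rows)

    line_v = sheet["_line"].to_numpy(float)
    treat_v = sheet["_treat"].to_numpy(float)
    day_codes = sheet["day"].astype("category").cat.codes.to_numpy()
    day_effects = rng.normal(0.0, config.sigma_day, size=n_rep)

    mu = truth["mu"].to_numpy()[:, None]
    a = truth["a"].to_numpy()[:, None]
    b = truth["b"].to_numpy()[:, None]
    c = truth["c"].to_numpy()[:, None]
    signal = (
        mu
        + a * line_v[None, :]
        + b * treat_v[None, :]
        + c * (line_v * treat_v)[None, :]
        + day_effects[day_codes][None, :]
    )
    noise_a = rng.normal(0.0, config.sigma_noise, size=signal.shape)
    noise_b = rng.normal(0.0, config.platform2_sigma, size=signal.shape)
    matrix_a = pd.DataFrame(
        signal + noise_a, index=truth.index, columns=sheet["sample_id"]
    )
    matrix_b = pd.DataFrame(
        config.platform2_gain * signal + config.platform2_offset + noise_b,
        index=truth.index,
        columns=sheet["sample_id"],
    )
    sheet = sheet.drop(columns=["_line", "_treat"])
    return matrix_a, matrix_b, sheet, truth


# ---------------------------------------------------------------------------
# qPCR Ct tables
# ---------------------------------------------------------------------------


@dataclass
class QpcrSimConfig:
    """Configuration of the qPCR Ct simulator.

    ``fold_changes`` maps gene -> relative abundance in the test group
    versus the calibrator group (a fold of 4 means the test group has
    4x the transcript and a Ct lower by 2 cycles).  Technical
    triplicates per biological sample follow the qPCR convention.
    """

    fold_changes: dict[str, float] = field(default_factory=lambda: {"MCU": 2.0, "TRPV6": 0.5})
    groups: tuple[str, str] = ("HT29", "NCM460")  # (test, calibrator)
    n_samples: int = 3
    n_replicates: int = 3
    sigma_ct: float = 0.2
    baseline_ct: float = 25.0
    housekeeping: str = "RP18S"
    housekeeping_ct: float = 12.0
    seed: int = 0

    def validate(self) -> None:
        for gene, fold in self.fold_changes.items():
            if fold <= 0:
                raise ValueError(f"nonpositive abundance fold for {gene}")
        if self.n_samples < 1 or self.n_replicates < 1:
            raise ValueError("replicate counts must be >= 1")
        if self.sigma_ct < 0:
            raise ValueError("sigma_ct must be >= 0")


def simulate_qpcr(config: QpcrSimConfig) -> pd.DataFrame:
    """Generate a long-format Ct table.

    Columns: gene, group, sample, replicate, ct, is_housekeeping.
    Target genes in the test group have Ct lowered by log2(fold); the
    housekeeping gene has constant abundance everywhere.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    test_group, calibrator = config.groups
    rows = []
    for group in (test_group, calibrator):
        for s in range(config.n_samples):
            sample = f"{group}_s{s + 1}"
            for gene, fold in config.fold_changes.items():
                shift = -np.log2(fold) if group == test_group else 0.0
                for r in range(config.n_replicates):
                    rows.append(
                        {
                            "gene": gene,
                            "group": group,
                            "sample": sample,
                            "replicate": r + 1,
                            "ct": config.baseline_ct
                            + shift
                            + rng.normal(0.0, config.sigma_ct),
                            "is_housekeeping": False,
                        }
                    )
            for r in range(config.n_replicates):
                rows.append(
                    {
                        "gene": config.housekeeping,
                        "group": group,
                        "sample": sample,
                        "replicate": r + 1,
                        "ct": config.housekeeping_ct + rng.normal(0.0, config.sigma_ct),
                        "is_housekeeping": True,
                    }
                )
    return pd.DataFrame(rows)
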