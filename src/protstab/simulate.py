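"""Synthetic pulsed-SILAC cohorts with known ground truth.

Generates everything the downstream analysis consumes — isotope-ratio
trajectories, protein sequences, per-residue disorder calls, an
interaction network and a labeled feature table — with the statistical
structure the pipeline assumes: per-protein exponential ratio decay
``y(t) = A*exp(-t*(lam_dil+lam_deg)) + B`` with additive Gaussian
observation noise and random dropout of time points; half-lives drawn
from a two-component normal mixture on the log2-minute scale (the
slow-degrading component around 2^7.64 ~ 200 min and the fast component
around 2^5.58 ~ 48 min); and a preferential-attachment interaction
network in which a chosen stability class can be made stochastically
more connected.

Defaults reflect a bacterial culture dividing every 60 minutes sampled
at 0, 15, 60, 120, 180 and 240 minutes after the label switch.
"""

from __future__ import annotations


from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kinetics import LN2, IsotopeRatioSeries

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

STABLE, SLOW, FAST = "stable", "slow", "fast"

#: Target disordered-residue fraction per stability class. Fast-degrading
#: proteins are simulated as more disordered, mirroring the association
#: between intrinsic disorder and degradation propensity.
DISORDER_FRACTION = {STABLE: 0.05, SLOW: 0.08, FAST: 0.16}


@dataclass
class SimulationConfig:
    """Study-condition parameters for cohort generation.

    ``slow_mix`` / ``fast_mix`` are (mean, sd) of log2 half-life in
    minutes. ``noise_sd`` is the SD of additive Gaussian noise on the
    normalized ratios. ``a_range`` and ``b_range`` are uniform sampling
    intervals for the per-protein amplitude A and recycling offset B,
    chosen so A + B <= 1 and the clean ratios stay within [0, 1].
    """

    n_stable: int = 200
    n_slow: int = 60
    n_fast: int = 20
    timepoints_min: tuple = (0.0, 15.0, 60.0, 120.0, 180.0, 240.0)
    t_cc_min: float = 60.0
    noise_sd: float = 0.02
    missing_prob: float = 0.15
    slow_mix: tuple = (7.64, 0.72)
    fast_mix: tuple = (5.58, 2.0)
    a_range: tuple = (0.85, 0.95)
    b_range: tuple = (0.0, 0.05)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_stable, self.n_slow, self.n_fast) < 0:
            raise ValueError("class counts must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0 <= self.missing_prob < 1:
            raise ValueError("missing_prob must lie in [0, 1)")
        tp = tuple(float(t) for t in self.timepoints_min)
        if tp != tuple(sorted(tp)) or tp[0] != 0:
            raise ValueError("timepoints must be sorted ascending and start at 0")
        self.timepoints_min = tp
        if self.t_cc_min <= 0:
            raise ValueError("t_cc_min must be positive")

    @property
    def lam_dil(self) -> float:
        return LN2 / self.t_cc_min


@dataclass
class SyntheticCohort:
    """A complete simulated input set with ground truth."""

    truth: pd.DataFrame        # protein_id, true_class, lam_deg, A, B, half_life_min
    trajectories: pd.DataFrame  # protein_id, time_min, ratio_ML, ratio_HL, n_peptides
    sequences: pd.DataFrame    # protein_id, sequence
    edges: pd.DataFrame        # id_a, id_b
    disorder: pd.DataFrame     # protein_id, disorder (string of 0/1)
    config: SimulationConfig

    def series_list(self) -> list[IsotopeRatioSeries]:
        out = []
        pep = self.truth.set_index("protein_id")
        for pid, grp in self.trajectories.groupby("protein_id", sort=False):
            out.append(
                IsotopeRatioSeries(
                    protein_id=pid,
                    t=grp["time_min"].to_numpy(),
                    ratio_ML=grp["ratio_ML"].to_numpy(),
                    ratio_HL=grp["ratio_HL"].to_numpy(),
                    n_peptides=int(grp["n_peptides"].iloc[0]),
                )
            )
        del pep
        return out


def sample_half_lives(
    n_slow: int,
    n_fast: int,
    slow_mix: tuple = (7.64, 0.72),
    fast_mix: tuple = (5.58, 2.0),
    seed: int | np.random.Generator = 0,
) -> list[tuple[str, float]]:
    """Draw half-lives (minutes) from the two-component log2-normal mixture.

    Each draw is N(mean, sd) on the log2-minute scale, exponentiated to
    minutes. Returns ``n_slow + n_fast`` (class, half-life) pairs, slow
    first.
    """
    if n_slow < 0 or n_fast < 0:
        raise ValueError("counts must be non-negative")
    rng = _as_rng(seed)
    out: list[tuple[str, float]] = []
    for cls, n, (mu, sd) in ((SLOW, n_slow, slow_mix), (FAST, n_fast, fast_mix)):
        draws = rng.normal(mu, sd, size=n)
        out.extend((cls, float(2.0 ** d)) for d in draws)
    return out


def simulate_trajectory(
    A: float,
    B: float,
    lam_deg: float,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    protein_id: str = "SIM",
    n_peptides: int = 3,
) -> IsotopeRatioSeries:
    """Simulate one protein's noisy M/L and H/L trajectory.

    The clean value at each kept time point is
    ``A*exp(-t*(lam_dil+lam_deg)) + B``; the clean H/L is its complement
    ``1 - M/L`` so that the pair sums to 1 before noise. Independent
    Gaussian noise of SD ``config.noise_sd`` is then added to each ratio
    and the noisy values are clipped to [0, 1]. Every non-zero time
    point is independently dropped with probability
    ``config.missing_prob``; t = 0 is always observed.
    """
    if lam_deg < 0:
        raise ValueError("lam_deg must be non-negative")
    if not (np.isfinite(A) and np.isfinite(B)):
        raise ValueError("A and B must be finite")
    rng = _as_rng(rng if rng is not None else config.seed)
    t = np.asarray(config.timepoints_min, dtype=float)
    keep = np.ones(len(t), dtype=bool)
    if config.missing_prob > 0:
        keep[1:] = rng.random(len(t) - 1) >= config.missing_prob
    t = t[keep]
    clean_ml = A * np.exp(-t * (config.lam_dil + lam_deg)) + B
    clean_hl = 1.0 - clean_ml
    if config.noise_sd > 0:
        ml = clean_ml + rng.normal(0.0, config.noise_sd, size=len(t))
        hl = clean_hl + rng.normal(0.0, config.noise_sd, size=len(t))
        ml = np.clip(ml, 0.0, 1.0)
        hl = np.clip(hl, 0.0, 1.0)
    else:
        ml, hl = clean_ml, clean_hl
    return IsotopeRatioSeries(
        protein_id=protein_id,
        t=t,
        ratio_ML=ml,
        ratio_HL=hl,
        n_peptides=n_peptides,
    )


def simulate_feature_table(
    n_per_class: dict[str, int],
    n_informative: int = 5,
    effect_size: float = 1.0,
    n_noise: int = 45,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Class-labeled Gaussian feature table for classifier testing.

    Informative columns are standard Gaussians shifted by
    ``class_index * effect_size`` per class; noise columns are iid
    standard Gaussians in every class.
    """
    if effect_size < 0:
        raise ValueError("effect_size must be non-negative")
    if n_informative + n_noise < 1:
        raise ValueError("need at least one feature column")
    rng = _as_rng(seed)
    frames, labels = [], []
    for ci, (cls, n) in enumerate(sorted(n_per_class.items())):
        block = rng.normal(size=(n, n_informative + n_noise))
        block[:, :n_informative] += ci * effect_size
        frames.append(block)
        labels.extend([cls] * n)
    cols = [f"inf_{i:02d}" for i in range(n_informative)] + [
        f"noise_{i:02d}" for i in range(n_noise)
    ]
    X = pd.DataFrame(np.vstack(frames) if frames else np.empty((0, len(cols))),
                     columns=cols)
    return X, pd.Series(labels, name="label")


def simulate_ppin(
    n_nodes: int,
    m_attach: int = 2,
    degree_boost: dict[str, float] | None = None,
    labels: list[str] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Preferential-attachment interaction network with class-biased degree.

    Nodes arrive one at a time and attach to ``m_attach`` distinct
    existing nodes with probability proportional to
    ``(degree + 1) * degree_boost[class]``, so a boosted class
    accumulates stochastically larger degree. Returns an undirected
    simple edge list (columns id_a, id_b) over node indices 0..n-1.
    """
    if n_nodes < 2:
        raise ValueError("need at least two nodes")
    if m_attach < 1:
        raise ValueError("m_attach must be >= 1")
    if m_attach >= n_nodes:
        raise ValueError("m_attach must be smaller than n_nodes")
    rng = _as_rng(seed)
    if labels is None:
        labels = [STABLE] * n_nodes
    if len(labels) != n_nodes:
        raise ValueError("labels must have one entry per node")
    boost = degree_boost or {}
    w_class = np.array([float(boost.get(c, 1.0)) for c in labels])
    degree = np.zeros(n_nodes, dtype=float)
    edges: list[tuple[int, int]] = []
    for new in range(m_attach, n_nodes):
        weights = (degree[:new] + 1.0) * w_class[:new]
        probs = weights / weights.sum()
        targets = rng.choice(new, size=min(m_attach, new), replace=False, p=probs)
        for tgt in targets:
            edges.append((int(tgt), new))
            degree[tgt] += 1
            degree[new] += 1
    return pd.DataFrame(edges, columns=["id_a", "id_b"])


def simulate_sequence(
    length: int,
    rng: np.random.Generator,
    degron: str | None = None,
) -> str:
    """Random protein sequence: leading Met, then iid uniform residues.

    ``degron`` optionally plants a literal motif: a C-terminal signal if
    it ends the sequence (e.g. ``"LAA"`` or ``"RRKKAI"``) — pass it via
    :func:`plant_degron` for anchored placement.
    """
    if length < 2:
        raise ValueError("sequence length must be >= 2")
    body = rng.choice(list(AMINO_ACIDS), size=length - 1)
    seq = "M" + "".join(body)
    if degron:
        seq = plant_degron(seq, degron)
    return seq


def plant_degron(sequence: str, motif: str, terminus: str = "C") -> str:
    """Overwrite one terminus of ``sequence`` with a literal motif."""
    if len(motif) >= len(sequence):
        raise ValueError("motif longer than sequence")
    if terminus == "C":
        return sequence[: -len(motif)] + motif
    return motif + sequence[len(motif):]


def simulate_disorder(length: int, target_fraction: float,
                      rng: np.random.Generator, persistence: float = 0.9) -> str:
    """Two-state Markov chain of per-residue disorder calls.

    ``persistence`` is the probability of staying disordered, which
    produces contiguous disordered segments rather than salt-and-pepper
    calls; the entry probability is set so the stationary disordered
    fraction equals ``target_fraction``.
    """
    p_exit = 1.0 - persistence
    f = min(max(target_fraction, 0.0), 0.95)
    p_enter = p_exit * f / (1.0 - f)
    state = rng.random() < f
    calls = []
    for _ in range(length):
        calls.append("1" if state else "0")
        if state:
            state = rng.random() >= p_exit
        else:
            state = rng.random() < p_enter
    return "".join(calls)


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate a full labeled cohort from one master seed.

    Stable proteins have lam_deg = 0; slow/fast proteins get lam_deg =
    ln2 / t_half with half-lives drawn from the configured mixture.
    Sequences, disorder strings and a preferential-attachment network
    (slow-degrading proteins mildly more connected) are generated for
    every protein.
    """
    master = np.random.SeedSequence(config.seed)
    rng_hl, rng_traj, rng_seq, rng_net = (
        np.random.default_rng(s) for s in master.spawn(4)
    )

    classes = [STABLE] * config.n_stable
    lam_degs = [0.0] * config.n_stable
    # degradation rates are capped at the decay model's parameter space
    # (lam_deg <= 100 * lam_dil, i.e. half-life >= t_cc/100): rarer,
    # faster draws from the mixture tail describe proteins degraded to
    # nothing before the first sample and are not meaningful study
    # subjects
    lam_cap = 100.0 * config.lam_dil
    for cls, t_half in sample_half_lives(
        config.n_slow, config.n_fast, config.slow_mix, config.fast_mix, rng_hl
    ):
        classes.append(cls)
        lam_degs.append(min(LN2 / t_half, lam_cap))

    n = len(classes)
    ids = [f"SYN{i:05d}" for i in range(n)]
    a_vals = rng_hl.uniform(*config.a_range, size=n)
    b_vals = rng_hl.uniform(*config.b_range, size=n)

    truth = pd.DataFrame(
        {
            "protein_id": ids,
            "true_class": classes,
            "lam_deg": lam_degs,
            "A": a_vals,
            "B": b_vals,
            "half_life_min": [
                (LN2 / l) if l > 0 else np.nan for l in lam_degs
            ],
        }
    )

    traj_frames = []
    for pid, cls, lam, a, b in zip(ids, classes, lam_degs, a_vals, b_vals):
        n_pep = int(rng_traj.integers(2, 15))
        s = simulate_trajectory(
            a, b, lam, config, rng=rng_traj, protein_id=pid, n_peptides=n_pep
        )
        traj_frames.append(
            pd.DataFrame(
                {
                    "protein_id": pid,
                    "time_min": s.t,
                    "ratio_ML": s.ratio_ML,
                    "ratio_HL": s.ratio_HL,
                    "n_peptides": n_pep,
                }
            )
        )
    trajectories = pd.concat(traj_frames, ignore_index=True)

    lengths = rng_seq.integers(60, 600, size=n)
    sequences = pd.DataFrame(
        {
            "protein_id": ids,
            "sequence": [simulate_sequence(int(l), rng_seq) for l in lengths],
        }
    )
    disorder = pd.DataFrame(
        {
            "protein_id": ids,
            "disorder": [
                simulate_disorder(int(l), DISORDER_FRACTION[c], rng_seq)
                for l, c in zip(lengths, classes)
            ],
        }
    )

    if n >= 2:
        edge_idx = simulate_ppin(
            n,
            m_attach=2,
            degree_boost={SLOW: 2.0},
            labels=classes,
            seed=rng_net,
        )
        edges = pd.DataFrame(
            {
                "id_a": [ids[i] for i in edge_idx["id_a"]],
                "id_b": [ids[i] for i in edge_idx["id_b"]],
            }
        )
    else:
        edges = pd.DataFrame(columns=["id_a", "id_b"])

    return SyntheticCohort(truth, trajectories, sequences, edges, disorder, config)


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)
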