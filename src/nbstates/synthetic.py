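"""Ground-truth-known synthetic study data.

Emulates the statistical shape of a long naturalistic-movie fMRI study:
15 subjects x 3543 timepoints at TR = 2 s in 8 segments; 7 neocortical
networks of 5-24 parcels plus hippocampal (19/hemisphere) and amygdalar
(9/hemisphere) subregion sets; per-network 4-state hidden Markov chains
shared across subjects (states are stimulus-driven) with subject-specific
Gaussian emissions; a token stream whose latent topics couple to planted
state-presence at calibrated correlation levels; and 9-observer emotion
annotations with planted agreement.

Every output is a deterministic function of the configured seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from ._utils import check_partition, spawn_seeds, write_tsv
from .srt import Cue, format_srt
from .text import TokenTimeline, smooth_rows

DEFAULT_NETWORKS = [
    ("VIS", 17),
    ("SMN", 14),
    ("DAN", 13),
    ("VAN", 12),
    ("LIM", 5),
    ("FPC", 15),
    ("DN", 24),
]
DEFAULT_LIMBIC = {"HC": 19, "AM": 9}  # subregions per hemisphere
N_LIMBIC_PCS = 3

EMOTION_LABELS = [
    "anger", "fear", "happiness", "love", "sadness", "hope", "pride",
    "gratitude", "relief", "shame", "remorse", "disappointment", "pity",
    "gloating", "resentment", "admiration", "gratification", "satisfaction",
    "fears_confirmed", "hate", "distress", "joy",
]
PLACE_ATTRIBUTES = ["interior", "exterior", "day", "night"]
CHARACTERS = [f"char_{i:02d}" for i in range(1, 7)]
MISC_FLAGS = [f"flag_{i:02d}" for i in range(1, 17)]


def default_attribute_set():
    """The 52-attribute description set: names, kinds, categories."""
    attributes = (
        ["arousal", "direction", "valence_positive", "valence_negative"]
        + EMOTION_LABELS
        + PLACE_ATTRIBUTES
        + [f"presence_{c}" for c in CHARACTERS]
        + MISC_FLAGS
    )
    kinds = {a: "binary" for a in attributes}
    kinds["arousal"] = kinds["direction"] = "bipolar"
    kinds["valence_positive"] = kinds["valence_negative"] = "unipolar"
    categories = {a: "other" for a in attributes}
    for a in ["arousal", "direction", "valence_positive", "valence_negative"]:
        categories[a] = "emotion"
    for a in EMOTION_LABELS:
        categories[a] = "emotion"
    for a in PLACE_ATTRIBUTES:
        categories[a] = "place"
    return attributes, kinds, categories


@dataclass(frozen=True)
class CouplingSpec:
    """Couple one topic's activation to one combination state's presence."""

    topic: int
    network: str
    structure: str
    state: int
    rho: float


@dataclass(frozen=True)
class PlantedEpisode:
    character: str
    start_s: float
    end_s: float
    arousal: str  # high | low
    valence: str  # positive | negative
    direction: str  # self | other
    emotion: str


@dataclass
class GeneratorConfig:
    """Study-scale defaults; every field can be overridden for desk-scale runs."""

    n_subjects: int = 15
    n_timepoints: int = 3543
    tr_seconds: float = 2.0
    n_segments: int = 8
    networks: list = field(default_factory=lambda: list(DEFAULT_NETWORKS))
    limbic: dict = field(default_factory=lambda: dict(DEFAULT_LIMBIC))
    n_states: int = 4
    self_transition: float = 0.97
    mean_separation: float = 4.0  # min pairwise Mahalanobis distance
    limbic_latent_sd: tuple = (1.5, 1.0, 0.7)
    limbic_residual_sd: float = 0.3
    n_topics: int = 10
    n_topic_words: int = 8
    n_background_words: int = 120
    tokens_per_bin: float = 4.0  # Poisson rate
    zero_inflation: float = 0.3  # probability of a silent bin
    coupled_topic_weight: float = 0.5
    scenery_topic_weight: float = 0.3
    smoothing_window_minutes: float = 4.0  # scale at which coupling is calibrated
    coupling: list = None  # list[CouplingSpec]; default set below
    n_observers: int = 9
    agreement: float = 0.8
    n_episodes: int = 120
    episode_duration_s: tuple = (10.0, 60.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_timepoints < 1 or self.n_states < 1:
            raise ValueError("counts must be positive")
        if self.coupling is None:
            target = self.networks[-1][0]  # highest associative network analog
            self.coupling = [
                CouplingSpec(k, target, "HC", k % self.n_states, 0.5)
                for k in range(min(self.n_states, self.n_topics))
            ]
        for c in self.coupling:
            if not 0.0 < c.rho < 1.0:
                raise ValueError(f"target rho must be in (0, 1), got {c.rho}")


@dataclass
class GroundTruth:
    """All planted quantities needed to test every downstream stage."""

    config: GeneratorConfig
    segment_bounds: list
    hmm_params: dict  # (network, structure) -> dict(pi, Theta, means, covars)
    state_seqs: dict  # network -> (T,) int array, shared across subjects
    limbic_components: dict  # structure -> (3, m) orthonormal rows
    vocabulary: list
    topic_word_probs: np.ndarray  # (n_topics, V)
    background_probs: np.ndarray  # (V,)
    scenery_activations: np.ndarray  # (T, n_uncoupled) in [0, 1]
    episodes: list  # list[PlantedEpisode]
    attribute_set: tuple  # (attributes, kinds, categories)
    passthrough: dict  # binary place/other series, attribute -> (T,) array

    @property
    def combinations(self) -> list:
        return [
            (name, structure)
            for name, _ in self.config.networks
            for structure in self.config.limbic
        ]

    @property
    def coupled_state_presence(self) -> dict:
        """CouplingSpec -> planted 0/1 presence series of its target state."""
        out = {}
        for c in self.config.coupling:
            out[c] = (self.state_seqs[c.network] == c.state).astype(float)
        return out


def stationary_distribution(Theta: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix (left eigenvector)."""
    vals, vecs = np.linalg.eig(Theta.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def _random_spd(rng: np.random.Generator, r: int) -> np.ndarray:
    """Diagonal-dominant SPD covariance: identity plus a low-weight Wishart part."""
    A = rng.standard_normal((r, r)) * (0.3 / np.sqrt(r))
    return np.eye(r) + A @ A.T


def _separated_means(
    rng: np.random.Generator, n: int, r: int, cov: np.ndarray, separation: float
) -> np.ndarray:
    """n mean vectors with min pairwise Mahalanobis distance == separation."""
    means = rng.standard_normal((n, r))
    means -= means.mean(axis=0)
    Linv = np.linalg.inv(np.linalg.cholesky(cov))
    white = means @ Linv.T
    dmin = np.inf
    for i in range(n):
        for j in range(i + 1, n):
            dmin = min(dmin, float(np.linalg.norm(white[i] - white[j])))
    if dmin <= 0:
        raise ValueError("degenerate mean draw")
    return means * (separation / dmin)


def _orthonormal_rows(rng: np.random.Generator, k: int, m: int) -> np.ndarray:
    q, _ = np.linalg.qr(rng.standard_normal((m, k)))
    comps = q.T
    for i in range(k):
        j = int(np.argmax(np.abs(comps[i])))
        if comps[i, j] < 0:
            comps[i] = -comps[i]
    return comps


def generate_ground_truth(config: GeneratorConfig | None = None, **overrides) -> GroundTruth:
    """Build the full planted-parameter set for one synthetic study."""
    if config is None:
        config = GeneratorConfig(**overrides)
    elif overrides:
        config = replace(config, **overrides)
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    T = cfg.n_timepoints
    edges = np.linspace(0, T, cfg.n_segments + 1).astype(int)
    segment_bounds = [(int(a), int(b)) for a, b in zip(edges[:-1], edges[1:])]
    check_partition(segment_bounds, T)

    # per-network chains, shared across subjects (stimulus-driven states)
    state_seqs: dict = {}
    chains: dict = {}
    for name, _ in cfg.networks:
        n = cfg.n_states
        off = rng.dirichlet(np.full(n - 1, 5.0), size=n) * (1.0 - cfg.self_transition)
        Theta = np.zeros((n, n))
        for k in range(n):
            Theta[k, [j for j in range(n) if j != k]] = off[k]
            Theta[k, k] = cfg.self_transition
        pi = stationary_distribution(Theta)
        seq = np.empty(T, dtype=int)
        seq[0] = rng.choice(n, p=pi)
        for t in range(1, T):
            seq[t] = rng.choice(n, p=Theta[seq[t - 1]])
        chains[name] = (pi, Theta)
        state_seqs[name] = seq

    # limbic latent structure shared across combinations of one structure
    limbic_components = {
        structure: _orthonormal_rows(rng, N_LIMBIC_PCS, m)
        for structure, m in cfg.limbic.items()
    }
    latent_var = np.asarray(cfg.limbic_latent_sd, dtype=float) ** 2
    D = np.diag(np.concatenate([latent_var, latent_var]))  # L then R PCs

    hmm_params: dict = {}
    for name, r_net in cfg.networks:
        pi, Theta = chains[name]
        cov_net = np.stack([_random_spd(rng, r_net) for _ in range(cfg.n_states)])
        pooled = cov_net.mean(axis=0)
        mu_net = _separated_means(rng, cfg.n_states, r_net, pooled, cfg.mean_separation)
        for structure in cfg.limbic:
            R = r_net + 2 * N_LIMBIC_PCS
            means = np.zeros((cfg.n_states, R))
            means[:, :r_net] = mu_net
            covars = np.zeros((cfg.n_states, R, R))
            for k in range(cfg.n_states):
                covars[k, :r_net, :r_net] = cov_net[k]
                covars[k, r_net:, r_net:] = D
            hmm_params[(name, structure)] = {
                "pi": pi.copy(),
                "Theta": Theta.copy(),
                "means": means,
                "covars": covars,
            }

    # vocabulary: exclusive topic words plus a Zipf-weighted background
    topic_words = [
        f"topic{j:02d}w{i}" for j in range(cfg.n_topics) for i in range(cfg.n_topic_words)
    ]
    background_words = [f"word{i:03d}" for i in range(cfg.n_background_words)]
    vocabulary = sorted(topic_words + background_words)
    vidx = {w: i for i, w in enumerate(vocabulary)}
    V = len(vocabulary)
    topic_word_probs = np.zeros((cfg.n_topics, V))
    for j in range(cfg.n_topics):
        weights = rng.dirichlet(np.full(cfg.n_topic_words, 2.0))
        for i in range(cfg.n_topic_words):
            topic_word_probs[j, vidx[f"topic{j:02d}w{i}"]] = weights[i]
    background_probs = np.zeros(V)
    zipf = 1.0 / np.arange(1, cfg.n_background_words + 1)
    zipf /= zipf.sum()
    for i, w in enumerate(background_words):
        background_probs[vidx[w]] = zipf[i]

    # scenery (uncoupled) topic activations: sums of smooth bumps in [0, 1]
    coupled_topics = {c.topic for c in cfg.coupling}
    n_scenery = cfg.n_topics - len(coupled_topics)
    tgrid = np.arange(T, dtype=float)
    width = max(cfg.smoothing_window_minutes * 60.0 / cfg.tr_seconds / 2.0, 5.0)
    scenery = np.zeros((T, n_scenery))
    for j in range(n_scenery):
        n_bumps = max(int(rng.integers(3, 9)), 1)
        centers = rng.uniform(0, T, size=n_bumps)
        for c0 in centers:
            scenery[:, j] += np.exp(-0.5 * ((tgrid - c0) / width) ** 2)
        peak = scenery[:, j].max()
        if peak > 0:
            scenery[:, j] /= peak

    # planted emotional episodes
    duration = T * cfg.tr_seconds
    episodes = []
    for _ in range(cfg.n_episodes):
        d = rng.uniform(*cfg.episode_duration_s)
        start = rng.uniform(0, max(duration - d, 1e-9))
        episodes.append(
            PlantedEpisode(
                character=CHARACTERS[int(rng.integers(len(CHARACTERS)))],
                start_s=float(start),
                end_s=float(start + d),
                arousal=("high" if rng.random() < 0.5 else "low"),
                valence=("positive" if rng.random() < 0.5 else "negative"),
                direction=("self" if rng.random() < 0.5 else "other"),
                emotion=EMOTION_LABELS[int(rng.integers(len(EMOTION_LABELS)))],
            )
        )
    episodes.sort(key=lambda e: e.start_s)

    # binary passthrough series: place/time scene blocks, character presence,
    # miscellaneous narrative flags
    attributes, kinds, categories = default_attribute_set()
    passthrough: dict = {}
    interior = np.zeros(T)
    day = np.zeros(T)
    t = 0
    while t < T:
        block = int(rng.integers(10, 40))
        interior[t : t + block] = float(rng.random() < 0.6)
        day[t : t + block] = float(rng.random() < 0.7)
        t += block
    passthrough["interior"] = interior
    passthrough["exterior"] = 1.0 - interior
    passthrough["day"] = day
    passthrough["night"] = 1.0 - day
    for ch in CHARACTERS:
        series = np.zeros(T)
        for ep in episodes:
            if ep.character == ch:
                a = int(ep.start_s / cfg.tr_seconds)
                b = int(np.ceil(ep.end_s / cfg.tr_seconds))
                series[a : min(b, T)] = 1.0
        passthrough[f"presence_{ch}"] = series
    for flag in MISC_FLAGS:
        series = np.zeros(T)
        t = 0
        while t < T:
            block = int(rng.integers(15, 60))
            series[t : t + block] = float(rng.random() < 0.3)
            t += block
        passthrough[flag] = series

    return GroundTruth(
        config=cfg,
        segment_bounds=segment_bounds,
        hmm_params=hmm_params,
        state_seqs=state_seqs,
        limbic_components=limbic_components,
        vocabulary=vocabulary,
        topic_word_probs=topic_word_probs,
        background_probs=background_probs,
        scenery_activations=scenery,
        episodes=episodes,
        attribute_set=(attributes, kinds, categories),
        passthrough=passthrough,
    )


@dataclass
class SubjectData:
    """One subject's raw subregion table plus everything needed for recovery tests."""

    subject_id: int
    table: pd.DataFrame  # T x total subregions
    region_meta: pd.DataFrame  # subregion_id, structure, hemisphere, network
    state_seqs: dict  # (network, structure) -> shared planted sequence
    combination_features: dict  # (network, structure) -> T x R feature matrix
    limbic_latents: dict  # structure -> T x 6 latent PCs (L then R)


def simulate_subject_timeseries(
    gt: GroundTruth, subject_id: int, seed: int | None = None
) -> SubjectData:
    """Sample one subject's subregion series from the planted model.

    Network parcels are Gaussian emissions of the shared per-network chain;
    limbic subregions are low-rank images of white latent PCs (shared
    component matrix across hemispheres) plus isotropic residual noise.
    """
    cfg = gt.config
    if not 0 <= subject_id < cfg.n_subjects:
        raise ValueError(f"subject_id {subject_id} out of range")
    if seed is None:
        seed = cfg.seed
    rng = np.random.default_rng(
        np.random.SeedSequence([seed, 7919 + subject_id])
    )
    T = cfg.n_timepoints
    columns: dict[str, np.ndarray] = {}
    meta_rows = []
    parcel_blocks: dict[str, np.ndarray] = {}
    for name, r_net in cfg.networks:
        params = gt.hmm_params[(name, next(iter(cfg.limbic)))]
        seq = gt.state_seqs[name]
        X = np.empty((T, r_net))
        chols = [
            np.linalg.cholesky(params["covars"][k][:r_net, :r_net])
            for k in range(cfg.n_states)
        ]
        noise = rng.standard_normal((T, r_net))
        for k in range(cfg.n_states):
            mask = seq == k
            X[mask] = params["means"][k, :r_net] + noise[mask] @ chols[k].T
        parcel_blocks[name] = X
        for j in range(r_net):
            label = f"{name}_p{j:02d}"
            columns[label] = X[:, j]
            meta_rows.append(
                {
                    "subregion_id": label,
                    "structure": "neocortex",
                    "hemisphere": "both",
                    "network": name,
                }
            )
    latent_sd = np.asarray(cfg.limbic_latent_sd, dtype=float)
    limbic_latents: dict[str, np.ndarray] = {}
    for structure, m in cfg.limbic.items():
        comps = gt.limbic_components[structure]
        lat = rng.standard_normal((T, 2 * N_LIMBIC_PCS)) * np.tile(latent_sd, 2)
        limbic_latents[structure] = lat
        for hemi, sl in (("L", slice(0, N_LIMBIC_PCS)), ("R", slice(N_LIMBIC_PCS, None))):
            block = lat[:, sl] @ comps + cfg.limbic_residual_sd * rng.standard_normal(
                (T, m)
            )
            for j in range(m):
                label = f"{structure}_{hemi}_s{j:02d}"
                columns[label] = block[:, j]
                meta_rows.append(
                    {
                        "subregion_id": label,
                        "structure": structure,
                        "hemisphere": hemi,
                        "network": "",
                    }
                )
    table = pd.DataFrame(columns)
    meta = pd.DataFrame(meta_rows)
    combination_features = {}
    state_seqs = {}
    for name, r_net in cfg.networks:
        for structure in cfg.limbic:
            combination_features[(name, structure)] = np.hstack(
                [parcel_blocks[name], limbic_latents[structure]]
            )
            state_seqs[(name, structure)] = gt.state_seqs[name]
    return SubjectData(
        subject_id=subject_id,
        table=table,
        region_meta=meta,
        state_seqs=state_seqs,
        combination_features=combination_features,
        limbic_latents=limbic_latents,
    )


def _smoothing_half_bins(cfg: GeneratorConfig) -> int:
    return int(np.floor(cfg.smoothing_window_minutes * 60.0 / 2.0 / cfg.tr_seconds))


def _decoy_activation(T: int, self_transition: float, seed: int) -> np.ndarray:
    """An independent two-state on/off chain with ~25% occupancy, used to
    dilute a coupled topic's state-locking without thinning its tokens."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 900001]))
    p_on = 0.25
    stay_on = self_transition
    stay_off = 1.0 - (1.0 - stay_on) * p_on / (1.0 - p_on)
    xi = np.empty(T)
    xi[0] = float(rng.random() < p_on)
    for t in range(1, T):
        stay = stay_on if xi[t - 1] else stay_off
        xi[t] = xi[t - 1] if rng.random() < stay else 1.0 - xi[t - 1]
    return xi


def _calibrate_coupling_slope(
    presence: np.ndarray,
    decoy: np.ndarray,
    target_rho: float,
    tokens_per_bin: float,
    zero_inflation: float,
    weight: float,
    half_bins: int,
    seed: int,
    n_iter: int = 22,
) -> float:
    """Bisect the state-locking fraction of a coupled topic's activation,
    ``u(t) = c * presence + (1 - c) * decoy``, so the smoothed topic-count
    series correlates with the planted presence at the target level.

    Candidate evaluation samples the topic count's exact marginal (Poisson
    thinning of the zero-inflated token total) with common random numbers;
    if the target exceeds the attainable maximum the slope saturates at 1.
    """
    n_draws = 6  # averaging tames the draw-to-draw noise of the criterion

    def realized(c: float) -> float:
        if presence.std() == 0:
            return 0.0
        w = weight * (c * presence + (1.0 - c) * decoy)
        rs = []
        for d in range(n_draws):
            rng = np.random.default_rng(np.random.SeedSequence([seed, 104729 + d]))
            silent = rng.random(presence.size) < zero_inflation
            counts = np.where(silent, 0, rng.poisson(tokens_per_bin * w))
            sm = smooth_rows(counts[:, None].astype(float), half_bins)[:, 0]
            rs.append(0.0 if sm.std() == 0 else float(np.corrcoef(sm, presence)[0, 1]))
        return float(np.mean(rs))

    if realized(1.0) <= target_rho:
        return 1.0
    lo, hi = 0.0, 1.0
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        if realized(mid) < target_rho:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_subtitle_stream(gt: GroundTruth, seed: int | None = None):
    """Sample the shared token stream and its SubRip serialization.

    Returns ``(timeline, srt_text, info)`` where ``info`` carries the
    per-topic mixture-weight trajectories and calibrated slopes.
    """
    cfg = gt.config
    if seed is None:
        seed = cfg.seed
    if cfg.n_topics < 1:
        raise ValueError("topic dictionary is empty")
    T = cfg.n_timepoints
    half_bins = _smoothing_half_bins(cfg)
    weights = np.zeros((T, cfg.n_topics))
    slopes: dict[int, float] = {}
    presence_by_topic = {c.topic: p for c, p in gt.coupled_state_presence.items()}
    rho_by_topic = {c.topic: c.rho for c in cfg.coupling}
    scenery_iter = iter(range(gt.scenery_activations.shape[1]))
    for j in range(cfg.n_topics):
        if j in presence_by_topic:
            presence = presence_by_topic[j]
            decoy = _decoy_activation(T, cfg.self_transition, seed + 31 * j)
            c = _calibrate_coupling_slope(
                presence,
                decoy,
                rho_by_topic[j],
                cfg.tokens_per_bin,
                cfg.zero_inflation,
                cfg.coupled_topic_weight,
                half_bins,
                seed=seed + j,
            )
            slopes[j] = c
            weights[:, j] = cfg.coupled_topic_weight * (
                c * presence + (1.0 - c) * decoy
            )
        else:
            col = next(scenery_iter)
            weights[:, j] = cfg.scenery_topic_weight * gt.scenery_activations[:, col]
    # cap total topic mass; the remainder goes to the background distribution
    total = weights.sum(axis=1)
    over = total > 0.9
    if over.any():
        weights[over] *= (0.9 / total[over])[:, None]

    rng = np.random.default_rng(np.random.SeedSequence([seed, 15485863]))
    tokens: list[list[str]] = []
    vocab = np.asarray(gt.vocabulary, dtype=object)
    for t in range(T):
        if rng.random() < cfg.zero_inflation:
            tokens.append([])
            continue
        n_tok = int(rng.poisson(cfg.tokens_per_bin))
        if n_tok == 0:
            tokens.append([])
            continue
        w = weights[t]
        probs = np.concatenate([w, [1.0 - w.sum()]])
        sources = rng.choice(cfg.n_topics + 1, size=n_tok, p=probs)
        bin_tokens = []
        for src in sources:
            dist = (
                gt.background_probs if src == cfg.n_topics else gt.topic_word_probs[src]
            )
            bin_tokens.append(str(rng.choice(vocab, p=dist)))
        tokens.append(bin_tokens)
    timeline = TokenTimeline(T, cfg.tr_seconds, tokens)
    cues = [
        Cue(t + 1, t * cfg.tr_seconds, (t + 1) * cfg.tr_seconds, " ".join(toks))
        for t, toks in enumerate(tokens)
        if toks
    ]
    info = {"weights": weights, "slopes": slopes, "half_bins": half_bins}
    return timeline, format_srt(cues), info


def simulate_observer_annotations(
    gt: GroundTruth, n_observers: int | None = None, seed: int | None = None
) -> pd.DataFrame:
    """Each observer independently marks each planted episode's attributes
    with the configured agreement probability."""
    cfg = gt.config
    if n_observers is None:
        n_observers = cfg.n_observers
    if n_observers < 1:
        raise ValueError("n_observers must be >= 1")
    if seed is None:
        seed = cfg.seed
    rng = np.random.default_rng(np.random.SeedSequence([seed, 32452843]))
    p = cfg.agreement
    rows = []
    for ep in gt.episodes:
        marks = [
            ("arousal", ep.arousal),
            ("valence", ep.valence),
            ("direction", ep.direction),
            (ep.emotion, "present"),
        ]
        for obs in range(1, n_observers + 1):
            for attribute, value in marks:
                if rng.random() < p:
                    rows.append(
                        {
                            "observer_id": obs,
                            "character": ep.character,
                            "attribute": attribute,
                            "start_s": ep.start_s,
                            "end_s": ep.end_s,
                            "value": value,
                        }
                    )
    return pd.DataFrame(
        rows,
        columns=["observer_id", "character", "attribute", "start_s", "end_s", "value"],
    )


def write_outputs(gt: GroundTruth, out_dir, seed: int | None = None) -> dict:
    """Write subject tables, region metadata, SRT, annotations and a
    ground-truth JSON summary; returns the path map."""
    cfg = gt.config
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if seed is None:
        seed = cfg.seed
    paths: dict = {"subjects": []}
    meta_written = False
    for i in range(cfg.n_subjects):
        sub = simulate_subject_timeseries(gt, i, seed=seed)
        p = out / f"subject_{i:02d}_timeseries.tsv"
        write_tsv(sub.table, p)
        paths["subjects"].append(str(p))
        if not meta_written:
            write_tsv(sub.region_meta, out / "region_metadata.tsv")
            paths["region_metadata"] = str(out / "region_metadata.tsv")
            meta_written = True
    _, srt_text, _ = simulate_subtitle_stream(gt, seed=seed)
    (out / "subtitles.srt").write_text(srt_text)
    paths["subtitles"] = str(out / "subtitles.srt")
    intervals = simulate_observer_annotations(gt, seed=seed)
    write_tsv(intervals, out / "observer_intervals.tsv")
    paths["observer_intervals"] = str(out / "observer_intervals.tsv")
    truth = {
        "seed": cfg.seed,
        "n_subjects": cfg.n_subjects,
        "n_timepoints": cfg.n_timepoints,
        "tr_seconds": cfg.tr_seconds,
        "segment_bounds": [list(b) for b in gt.segment_bounds],
        "networks": [list(x) for x in cfg.networks],
        "limbic": cfg.limbic,
        "n_states": cfg.n_states,
        "state_sequences": {k: v.tolist() for k, v in gt.state_seqs.items()},
        "coupling": [
            {
                "topic": c.topic,
                "network": c.network,
                "structure": c.structure,
                "state": c.state,
                "rho": c.rho,
            }
            for c in cfg.coupling
        ],
    }
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))
    paths["ground_truth"] = str(out / "ground_truth.json")
    return paths
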