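"""Synthetic fixtures with known ground truth.

Every input class the pipeline consumes can be generated here with planted
parameters, so each downstream stage has a parameter-recovery test that needs
no external download:

* two-condition (fed / fasted) gene abundance tables with planted fold changes
  and a labelled chemoreceptor family,
* a binary neuron x gene expression atlas with optional planted per-neuron
  enrichment,
* confocal-like image stacks containing one Gaussian soma over background,
* GCaMP-like recordings with planted transients and a 2-D trajectory that
  approaches a circular bacterial lawn,
* multinomial behavioral-assay counts with a known preference index.

All randomness is driven by ``numpy.random.default_rng(seed)``; a given seed
reproduces every fixture bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The 12 amphid sensory neuron classes of the C. elegans head sense organ.
AMPHID_NEURONS = (
    "ADF", "ADL", "AFD", "ASE", "ASG", "ASH",
    "ASI", "ASJ", "ASK", "AWA", "AWB", "AWC",
)

CHEMO_FAMILY = "chemoreceptor"
OTHER_FAMILY = "other"


@dataclass(frozen=True)
class DEGroundTruth:
    """Planted truth for one gene: its fasted/fed abundance ratio and family."""

    gene_id: str
    true_ratio: float
    family: str

    def __post_init__(self):
        if self.true_ratio <= 0:
            raise ValueError("true_ratio must be positive")


@dataclass(frozen=True)
class TransientTruth:
    """Planted calcium transient: onset, peak dF/F0 amplitude and kinetics.

    Kinetics are fixture parameters (double-exponential rise/decay), not
    claims about any particular indicator.
    """

    onset_time: float
    amplitude: float
    rise_tau: float = 0.4
    decay_tau: float = 2.5

    def __post_init__(self):
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if not (self.decay_tau > self.rise_tau > 0):
            raise ValueError("need decay_tau > rise_tau > 0")


@dataclass(frozen=True)
class LawnGeometry:
    """Circular bacterial lawn: center (x, y) in mm and radius in mm."""

    center: tuple[float, float]
    radius: float

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("radius must be positive")


@dataclass
class ImageStack:
    """3-D (z, y, x) intensity grid with physical pixel/step sizes in microns."""

    intensities: np.ndarray
    pixel_size: float = 0.3
    z_step: float = 0.5

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 3:
            raise ValueError("stack must be 3-D (z, y, x)")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")


@dataclass
class Recording:
    """Time-aligned fluorescence channels with optional position and lawn."""

    time: np.ndarray
    f_neuron: np.ndarray
    f_background: np.ndarray
    position: np.ndarray | None = None  # (n, 2) x/y in mm
    lawn: LawnGeometry | None = None
    encounter_frame: int | None = None

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.f_neuron = np.asarray(self.f_neuron, dtype=float)
        self.f_background = np.asarray(self.f_background, dtype=float)
        n = self.time.size
        if self.f_neuron.size != n or self.f_background.size != n:
            raise ValueError("series lengths differ")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if self.position is not None:
            self.position = np.asarray(self.position, dtype=float)
            if self.position.shape != (n, 2):
                raise ValueError("position must be (n_frames, 2)")


# ---------------------------------------------------------------------------
# expression table


def _lognormal_around(rng, mean, cv):
    """Lognormal draws with the given mean and coefficient of variation."""
    mean = np.asarray(mean, dtype=float)
    if cv == 0:
        return np.broadcast_to(mean, mean.shape).copy()
    sigma2 = np.log1p(cv**2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mean=mu, sigma=np.sqrt(sigma2))


def gen_expression_table(
    n_genes: int = 1000,
    chemo_fraction: float = 0.085,
    n_up_chemo: int = 0,
    n_up_other: int = 0,
    fold_range: tuple[float, float] = (5.0, 8.0),
    noise_cv: float = 0.1,
    n_replicates: int = 3,
    seed: int = 0,
    base_abundance: float = 100.0,
) -> tuple[pd.DataFrame, list[DEGroundTruth]]:
    """Simulate a fed/fasted ribotag-style abundance table.

    A fraction ``chemo_fraction`` of genes is labelled ``chemoreceptor``;
    ``n_up_chemo`` of those and ``n_up_other`` of the remaining genes are
    planted as fasting-upregulated with fasted/fed ratio drawn uniformly from
    ``fold_range``. Replicate abundances are lognormal around the condition
    mean with coefficient of variation ``noise_cv``.

    Returns a long-format table (gene_id, family, condition, replicate,
    abundance) and the per-gene ground truth.
    """
    rng = np.random.default_rng(seed)
    n_chemo = int(round(chemo_fraction * n_genes))
    n_other = n_genes - n_chemo
    if n_up_chemo > n_chemo:
        raise ValueError(f"n_up_chemo={n_up_chemo} exceeds chemoreceptor count {n_chemo}")
    if n_up_other > n_other:
        raise ValueError(f"n_up_other={n_up_other} exceeds non-family count {n_other}")
    if (n_up_chemo or n_up_other) and not fold_range[0] > 4:
        raise ValueError("planted fold_range lower bound must exceed 4")
    if fold_range[1] < fold_range[0]:
        raise ValueError("fold_range must be a non-empty interval")

    gene_ids = [f"chemo-{i:04d}" for i in range(n_chemo)]
    gene_ids += [f"gene-{i:04d}" for i in range(n_other)]
    families = [CHEMO_FAMILY] * n_chemo + [OTHER_FAMILY] * n_other

    ratios = np.ones(n_genes)
    n_up = n_up_chemo + n_up_other
    up_idx = np.concatenate([
        rng.choice(n_chemo, size=n_up_chemo, replace=False),
        n_chemo + rng.choice(n_other, size=n_up_other, replace=False),
    ]).astype(int)
    ratios[up_idx] = rng.uniform(fold_range[0], fold_range[1], size=n_up)

    # Gene-specific baseline abundance (fed mean); mild spread across genes.
    fed_mean = _lognormal_around(rng, np.full(n_genes, base_abundance), 0.5)
    fasted_mean = fed_mean * ratios

    rows = []
    for cond, means in (("fed", fed_mean), ("fasted", fasted_mean)):
        draws = _lognormal_around(
            rng, np.tile(means[:, None], (1, n_replicates)), noise_cv
        )
        for rep in range(n_replicates):
            rows.append(pd.DataFrame({
                "gene_id": gene_ids,
                "family": families,
                "condition": cond,
                "replicate": rep,
                "abundance": draws[:, rep],
            }))
    table = pd.concat(rows, ignore_index=True)
    truth = [
        DEGroundTruth(g, float(r), f)
        for g, r, f in zip(gene_ids, ratios, families)
    ]
    return table, truth


# ---------------------------------------------------------------------------
# neuron atlas


def gen_neuron_atlas(
    n_neurons: int = 12,
    genes=None,
    expressed_prob: float = 0.3,
    planted_neuron: str | None = None,
    planted_excess: float = 1.0,
    target_genes=None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a binary neuron x gene expression atlas.

    Each (neuron, gene) cell is Bernoulli(``expressed_prob``). If
    ``planted_neuron`` is given, its expression probability for the genes in
    ``target_genes`` (e.g. the fasting-upregulated family members) is
    multiplied by ``planted_excess``, capped at 1 — the planted per-neuron
    enrichment the downstream test should recover.

    Returns a DataFrame indexed by neuron label with one 0/1 column per gene.
    """
    if not 0 < expressed_prob < 1:
        raise ValueError("expressed_prob must lie strictly between 0 and 1")
    if genes is None:
        genes = [f"chemo-{i:04d}" for i in range(100)]
    genes = list(genes)
    if n_neurons <= len(AMPHID_NEURONS):
        neurons = list(AMPHID_NEURONS[:n_neurons])
    else:
        neurons = list(AMPHID_NEURONS) + [
            f"N{i:02d}" for i in range(n_neurons - len(AMPHID_NEURONS))
        ]
    if planted_neuron is not None and planted_neuron not in neurons:
        raise ValueError(f"planted_neuron {planted_neuron!r} not among neurons")
    target = set(target_genes) if target_genes is not None else set()

    rng = np.random.default_rng(seed)
    probs = np.full((len(neurons), len(genes)), expressed_prob)
    if planted_neuron is not None and target:
        i = neurons.index(planted_neuron)
        cols = [j for j, g in enumerate(genes) if g in target]
        probs[i, cols] = np.minimum(1.0, expressed_prob * planted_excess)
    mat = (rng.random(probs.shape) < probs).astype(int)
    return pd.DataFrame(mat, index=pd.Index(neurons, name="neuron"), columns=genes)


# ---------------------------------------------------------------------------
# image stack


def gen_image_stack(
    shape: tuple[int, int, int] = (20, 64, 64),
    background_level: float = 100.0,
    soma_amplitude: float = 100.0,
    soma_sigma: float = 3.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    center: tuple[int, int, int] | None = None,
) -> tuple[ImageStack, float]:
    """Simulate a confocal z-stack: uniform background plus one Gaussian soma.

    The soma is an isotropic Gaussian (sigma in voxels) centred on a voxel, so
    the noise-free peak equals ``background_level + soma_amplitude`` exactly.
    Gaussian read noise (sd ``noise_sd``) is added and the result clipped at 0.
    Returns the stack and the planted amplitude-above-background truth.
    """
    if background_level < 0 or soma_amplitude < 0 or noise_sd < 0:
        raise ValueError("levels must be non-negative")
    nz, ny, nx = shape
    rng = np.random.default_rng(seed)
    if center is None:
        # keep the soma at least 3 sigma from the lateral borders; the z
        # margin is clamped so thin stacks remain usable (max projection
        # only needs the peak plane inside the stack)
        margin = int(np.ceil(3 * soma_sigma))
        if 2 * margin >= min(ny, nx):
            raise ValueError("soma does not fit inside the stack")
        zmargin = min(margin, (nz - 1) // 2)
        center = (
            int(rng.integers(zmargin, nz - zmargin)),
            int(rng.integers(margin, ny - margin)),
            int(rng.integers(margin, nx - margin)),
        )
    zz, yy, xx = np.ogrid[:nz, :ny, :nx]
    d2 = ((zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2)
    img = background_level + soma_amplitude * np.exp(-d2 / (2.0 * soma_sigma**2))
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    stack = ImageStack(np.clip(img, 0.0, None))
    stack.soma_center = center  # truth attached for recovery tests
    return stack, float(soma_amplitude)


# ---------------------------------------------------------------------------
# GCaMP recording


def transient_kernel(t: np.ndarray, tr: TransientTruth) -> np.ndarray:
    """Difference-of-exponentials transient, normalized to unit peak.

    Normalizing to unit peak makes the planted ``amplitude`` directly
    comparable to the detected dF/F0 peak amplitude.
    """
    dt = np.asarray(t, dtype=float) - tr.onset_time
    k = np.where(
        dt >= 0,
        np.exp(-np.maximum(dt, 0) / tr.decay_tau)
        - np.exp(-np.maximum(dt, 0) / tr.rise_tau),
        0.0,
    )
    # closed-form peak of exp(-t/td) - exp(-t/tr)
    t_peak = tr.rise_tau * tr.decay_tau / (tr.decay_tau - tr.rise_tau) * np.log(
        tr.decay_tau / tr.rise_tau
    )
    peak = np.exp(-t_peak / tr.decay_tau) - np.exp(-t_peak / tr.rise_tau)
    return tr.amplitude * k / peak


def _approach_trajectory(n, dt, lawn, rng, start_distance=4.0, speed=0.15):
    """Biased random walk toward the lawn center with fixed step length.

    Outside the lawn the heading points at the center with small angular
    jitter; once inside, the walk continues with larger jitter but the radial
    coordinate is clamped inside the lawn, so the boundary is crossed exactly
    once.
    """
    cx, cy = lawn.center
    step = speed * dt
    theta0 = rng.uniform(0, 2 * np.pi)
    pos = np.empty((n, 2))
    pos[0] = (cx + (lawn.radius + start_distance) * np.cos(theta0),
              cy + (lawn.radius + start_distance) * np.sin(theta0))
    inside = False
    for i in range(1, n):
        x, y = pos[i - 1]
        if not inside:
            heading = np.arctan2(cy - y, cx - x) + rng.normal(0, 0.25)
        else:
            heading = rng.uniform(0, 2 * np.pi)
        nx_, ny_ = x + step * np.cos(heading), y + step * np.sin(heading)
        r = np.hypot(nx_ - cx, ny_ - cy)
        if inside and r > 0.9 * lawn.radius:
            # clamp inside the lawn after the encounter
            nx_ = cx + (nx_ - cx) * 0.9 * lawn.radius / r
            ny_ = cy + (ny_ - cy) * 0.9 * lawn.radius / r
            r = 0.9 * lawn.radius
        if r <= lawn.radius:
            inside = True
        pos[i] = (nx_, ny_)
    return pos


def gen_gcamp_recording(
    duration: float = 120.0,
    frame_rate: float = 10.0,
    transients: list[TransientTruth] = (),
    background: float = 50.0,
    baseline: float = 100.0,
    trajectory_mode: str = "approach_lawn",
    lawn: LawnGeometry | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[Recording, dict]:
    """Simulate a freely-moving GCaMP recording with planted transients.

    The neuron channel is ``background + baseline * (1 + sum of unit-peak
    transient kernels) + noise``; the background channel is ``background +
    noise``, so background subtraction recovers the pure signal. In
    ``approach_lawn`` mode the 2-D trajectory crosses the lawn boundary
    exactly once; the encounter frame is recorded in the truth dict.
    """
    if frame_rate <= 0:
        raise ValueError("frame_rate must be positive")
    transients = list(transients)
    for tr in transients:
        if not 0 <= tr.onset_time < duration:
            raise ValueError("transient onset outside the recording")
    if lawn is None:
        lawn = LawnGeometry(center=(0.0, 0.0), radius=1.5)

    rng = np.random.default_rng(seed)
    n = int(round(duration * frame_rate))
    dt = 1.0 / frame_rate
    time = np.arange(n) * dt

    signal = np.zeros(n)
    for tr in transients:
        signal += transient_kernel(time, tr)
    f_neuron = background + baseline * (1.0 + signal)
    f_bg = np.full(n, background, dtype=float)
    if noise_sd > 0:
        f_neuron = f_neuron + rng.normal(0, noise_sd, n)
        f_bg = f_bg + rng.normal(0, noise_sd, n)

    if trajectory_mode == "approach_lawn":
        pos = _approach_trajectory(n, dt, lawn, rng)
    elif trajectory_mode == "stationary":
        pos = np.tile(np.array(lawn.center) + np.array([lawn.radius + 1.0, 0.0]),
                      (n, 1))
    else:
        raise ValueError(f"unknown trajectory_mode {trajectory_mode!r}")

    dist = np.hypot(pos[:, 0] - lawn.center[0], pos[:, 1] - lawn.center[1]) - lawn.radius
    enc = np.flatnonzero(dist <= 0)
    encounter = int(enc[0]) if enc.size else None
    rec = Recording(time, f_neuron, f_bg, position=pos, lawn=lawn,
                    encounter_frame=encounter)
    truth = {
        "transients": transients,
        "baseline": baseline,
        "background": background,
        "encounter_frame": encounter,
        "encounter_time": None if encounter is None else float(time[encounter]),
    }
    return rec, truth


# ---------------------------------------------------------------------------
# assay counts


def gen_assay_counts(
    assay: str = "chemotaxis",
    true_index: float = 0.0,
    n_animals: int = 100,
    n_plates: int = 10,
    other_prob: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate per-plate endpoint counts for a behavioral assay.

    Counts are multinomial with cell probabilities chosen so the expected
    computed index equals ``true_index``:

    * ``chemotaxis``: index (odor - control) / total in [-1, 1]; requires
      ``|true_index| <= 1 - other_prob``.
    * ``food_choice``: index exp / (exp + control) in [0, 1]; ``other_prob``
      is the fraction scored outside both patches.
    """
    if not 0 <= other_prob < 1:
        raise ValueError("other_prob must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    if assay == "chemotaxis":
        if not -1 <= true_index <= 1:
            raise ValueError("chemotaxis true_index must lie in [-1, 1]")
        if abs(true_index) > 1 - other_prob:
            raise ValueError("|true_index| cannot exceed 1 - other_prob")
        p_odor = (1 - other_prob + true_index) / 2.0
        p_ctrl = (1 - other_prob - true_index) / 2.0
        probs = [p_odor, p_ctrl, other_prob]
        cols = ["n_odor", "n_control", "n_other"]
    elif assay == "food_choice":
        if not 0 <= true_index <= 1:
            raise ValueError("food_choice true_index must lie in [0, 1]")
        probs = [true_index * (1 - other_prob),
                 (1 - true_index) * (1 - other_prob), other_prob]
        cols = ["n_exp", "n_control", "n_other"]
    else:
        raise ValueError(f"unknown assay {assay!r}")
    counts = rng.multinomial(n_animals, probs, size=n_plates)
    df = pd.DataFrame(counts, columns=cols)
    df.insert(0, "plate_id", [f"plate-{i:03d}" for i in range(n_plates)])
    return df
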