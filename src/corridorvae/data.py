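"""The Corridors dataset: synthetic 13x13 binary images with two generative factors.

Each image contains two noisy vertical "corridors" -- one in the upper
section (rows 0-5), one in the lower section (rows 7-12) -- separated by an
all-white divider row.  The horizontal positions ``(x_UC, x_LC)`` of the two
corridors, each an integer in 0..12, are the two orthogonal factors of
variation.  Around the deterministic core column, white pixels are drawn as
independent Bernoulli samples whose success probability follows a Gaussian
profile centred on the corridor (sigma = 1.2 pixels), rescaled so that the
core column has probability one.

Datasets can be sampled with a uniform distribution over the 169 position
pairs (``balanced``) or with 10x oversampling of either the pairs with the
lower corridor on the left (``lower_left_10x``) or the pairs with aligned
corridors (``aligned_10x``).  Four classification labelings (T1-T4) and the
flat position label ``l = 13*x_UC + x_LC`` are attached to every image.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
import numpy as np
import pandas as pd
import yaml

GRID = 13
N_PAIRS = GRID * GRID  # 169 distinct position pairs

#: Order in which the four task labelings are stored in ``Dataset.task_labels``.
TASKS = ("T1", "T2", "T3", "T4")

#: Bin edges of the 25-class task: positions [0,1], [2,4], [5,7], [8,10], [11,12].
T4_BIN_EDGES = np.array([2, 5, 8, 11])

WEIGHTINGS = ("balanced", "lower_left_10x", "aligned_10x")


@dataclass(frozen=True)
class CorridorConfig:
    """Geometry and noise parameters of the image generator."""

    grid_size: int = GRID
    divider_row: int = 6
    sigma: float = 1.2
    #: "peak" rescales the Gaussian profile to 1 at the core column (the core
    #: is then deterministically white); "density" uses the raw Gaussian pdf
    #: capped at 1.
    profile: str = "peak"

    def __post_init__(self) -> None:
        if self.grid_size != GRID:
            raise ValueError("analyses assume a 13x13 grid")
        if not 0 <= self.divider_row < self.grid_size:
            raise ValueError("divider_row outside the grid")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.profile not in ("peak", "density"):
            raise ValueError(f"unknown profile form {self.profile!r}")

    @property
    def upper_rows(self) -> np.ndarray:
        return np.arange(0, self.divider_row)

    @property
    def lower_rows(self) -> np.ndarray:
        return np.arange(self.divider_row + 1, self.grid_size)


@dataclass(frozen=True)
class DatasetSpec:
    """Parameters fully determining a generated dataset."""

    n_images: int
    weighting: str = "balanced"
    seed: int = 0
    config: CorridorConfig = field(default_factory=CorridorConfig)

    def __post_init__(self) -> None:
        if self.n_images <= 0:
            raise ValueError("n_images must be positive")
        if self.weighting not in WEIGHTINGS:
            raise ValueError(
                f"unknown weighting {self.weighting!r}; expected one of {WEIGHTINGS}"
            )


@dataclass
class Dataset:
    """Realized images with position and task labels (one row per image)."""

    images: np.ndarray  # (N, 13, 13) uint8 in {0, 1}
    positions: np.ndarray  # (N, 2) ints: columns are (x_UC, x_LC)
    task_labels: np.ndarray  # (N, 4) ints, columns ordered as TASKS
    spec: DatasetSpec | None = None

    def __len__(self) -> int:
        return self.images.shape[0]

    @property
    def position_labels(self) -> np.ndarray:
        """Flat label l = 13 * x_UC + x_LC in 0..168."""
        return position_label(self.positions)

    def split(self, test_frac: float = 0.1, seed: int = 7) -> tuple["Dataset", "Dataset"]:
        """Stratified train/test split by position label."""
        rng = np.random.default_rng(seed)
        labels = self.position_labels
        test_mask = np.zeros(len(self), dtype=bool)
        for lab in np.unique(labels):
            idx = np.flatnonzero(labels == lab)
            rng.shuffle(idx)
            n_test = max(1, int(round(test_frac * idx.size))) if idx.size > 1 else 0
            test_mask[idx[:n_test]] = True
        return self._take(~test_mask), self._take(test_mask)

    def _take(self, mask: np.ndarray) -> "Dataset":
        return Dataset(self.images[mask], self.positions[mask],
                       self.task_labels[mask], self.spec)


def corridor_profile(mu: int, config: CorridorConfig = CorridorConfig()) -> np.ndarray:
    """Bernoulli success probability per column for a corridor centred at ``mu``.

    With the default "peak" form, p(x) = exp(-(x - mu)^2 / (2 sigma^2)), so the
    core column has p = 1 and is deterministically white.
    """
    if not 0 <= mu < config.grid_size:
        raise ValueError(f"corridor position {mu} outside 0..{config.grid_size - 1}")
    x = np.arange(config.grid_size, dtype=float)
    g = np.exp(-((x - mu) ** 2) / (2.0 * config.sigma**2))
    if config.profile == "density":
        g = np.minimum(g / (config.sigma * np.sqrt(2.0 * np.pi)), 1.0)
        g[mu] = 1.0  # core column stays deterministic
    return g


def _profile_table(config: CorridorConfig) -> np.ndarray:
    """(13, 13) table: row mu holds corridor_profile(mu)."""
    return np.stack([corridor_profile(mu, config) for mu in range(config.grid_size)])


def render_images(positions: np.ndarray, config: CorridorConfig,
                  rng: np.random.Generator) -> np.ndarray:
    """Render a batch of images, one per (x_UC, x_LC) row of ``positions``.

    Every non-core pixel of a section is an independent Bernoulli draw from
    the column profile of that section's corridor; the divider row and the
    core columns are deterministically white.
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=int))
    if positions.ndim != 2 or positions.shape[1] != 2:
        raise ValueError("positions must have shape (N, 2)")
    if positions.min() < 0 or positions.max() >= config.grid_size:
        raise ValueError("corridor positions outside 0..12")
    n = positions.shape[0]
    g = config.grid_size
    table = _profile_table(config)
    imgs = np.zeros((n, g, g), dtype=np.uint8)

    for rows, mus in ((config.upper_rows, positions[:, 0]),
                      (config.lower_rows, positions[:, 1])):
        probs = table[mus]  # (N, 13)
        draws = rng.random((n, rows.size, g)) < probs[:, None, :]
        imgs[:, rows, :] = draws.astype(np.uint8)
        imgs[np.arange(n)[:, None], rows[None, :], mus[:, None]] = 1

    imgs[:, config.divider_row, :] = 1
    return imgs


def render_image(positions: tuple[int, int], config: CorridorConfig,
                 rng: np.random.Generator) -> np.ndarray:
    """Render a single 13x13 image for one position pair."""
    return render_images(np.asarray(positions)[None, :], config, rng)[0]


def pair_probabilities(weighting: str) -> np.ndarray:
    """Probability of each of the 169 position pairs under a weighting scheme.

    Indexed by the flat label l = 13 * x_UC + x_LC.  Unbalanced schemes give
    the favoured pairs 10x the per-pair probability of the others.
    """
    if weighting not in WEIGHTINGS:
        raise ValueError(f"unknown weighting {weighting!r}")
    uc, lc = np.divmod(np.arange(N_PAIRS), GRID)
    w = np.ones(N_PAIRS)
    if weighting == "lower_left_10x":
        w[lc <= 6] = 10.0
    elif weighting == "aligned_10x":
        w[lc == uc] = 10.0
    return w / w.sum()


def sample_positions(weighting: str, rng: np.random.Generator,
                     size: int | None = None) -> np.ndarray:
    """Draw position pairs i.i.d. under a weighting scheme.

    Returns a (size, 2) array, or a single (2,) pair when ``size`` is None.
    """
    p = pair_probabilities(weighting)
    flat = rng.choice(N_PAIRS, size=size if size is not None else 1, p=p)
    pairs = np.stack(np.divmod(flat, GRID), axis=-1)
    return pairs[0] if size is None else pairs


def position_label(positions: np.ndarray) -> np.ndarray | int:
    """Flat position label l = 13 * x_UC + x_LC."""
    positions = np.asarray(positions, dtype=int)
    lab = GRID * positions[..., 0] + positions[..., 1]
    return int(lab) if lab.ndim == 0 else lab


def task_label(task: str, positions: np.ndarray) -> np.ndarray | int:
    """Class label(s) of one of the four tasks for the given position pair(s).

    T1: 1 iff x_UC <= x_LC (upper corridor left of / aligned with the lower).
    T2: 1 iff x_UC < 6, or x_UC >= 6 and x_LC >= 6.
    T3: 1 iff the corridors are aligned (x_UC == x_LC).
    T4: 25 classes, upper_bin * 5 + lower_bin with position bins
        [0,1], [2,4], [5,7], [8,10], [11,12].
    """
    positions = np.asarray(positions, dtype=int)
    uc, lc = positions[..., 0], positions[..., 1]
    if task == "T1":
        lab = (uc <= lc).astype(int)
    elif task == "T2":
        lab = ((uc < 6) | ((uc >= 6) & (lc >= 6))).astype(int)
    elif task == "T3":
        lab = (uc == lc).astype(int)
    elif task == "T4":
        lab = np.digitize(uc, T4_BIN_EDGES) * 5 + np.digitize(lc, T4_BIN_EDGES)
    else:
        raise ValueError(f"unknown task {task!r}; expected one of {TASKS}")
    return int(lab) if lab.ndim == 0 else lab


def n_classes(task: str) -> int:
    return 25 if task == "T4" else 2


def all_task_labels(positions: np.ndarray) -> np.ndarray:
    """(N, 4) matrix of T1..T4 labels."""
    return np.stack([task_label(t, positions) for t in TASKS], axis=-1)


def generate_dataset(spec: DatasetSpec) -> Dataset:
    """Sample a full dataset: i.i.d. position pairs, rendered images, labels."""
    rng = np.random.default_rng(spec.seed)
    positions = sample_positions(spec.weighting, rng, size=spec.n_images)
    images = render_images(positions, spec.config, rng)
    return Dataset(images, positions, all_task_labels(positions), spec)


# ---------------------------------------------------------------------------
# Archive I/O: compressed arrays + CSV metadata + YAML manifest


def write_dataset(dataset: Dataset, path: str) -> None:
    """Write a dataset archive.

    ``path`` is a directory holding ``arrays.npz`` (images, positions,
    task_labels), ``metadata.csv`` (one row per image) and ``manifest.yaml``
    (the generation spec).
    """
    os.makedirs(path, exist_ok=True)
    np.savez_compressed(os.path.join(path, "arrays.npz"),
                        images=dataset.images, positions=dataset.positions,
                        task_labels=dataset.task_labels)
    meta = pd.DataFrame({
        "index": np.arange(len(dataset)),
        "x_UC": dataset.positions[:, 0],
        "x_LC": dataset.positions[:, 1],
        "l": dataset.position_labels,
    })
    for k, t in enumerate(TASKS):
        meta[t] = dataset.task_labels[:, k]
    meta.to_csv(os.path.join(path, "metadata.csv"), index=False)
    spec = dataset.spec
    manifest = {
        "generator": "corridorvae",
        "n_images": len(dataset),
        "weighting": spec.weighting if spec else None,
        "seed": spec.seed if spec else None,
        "sigma": spec.config.sigma if spec else None,
        "profile": spec.config.profile if spec else None,
    }
    with open(os.path.join(path, "manifest.yaml"), "w") as fh:
        yaml.safe_dump(manifest, fh)


def read_dataset(path: str) -> Dataset:
    """Read a dataset archive written by :func:`write_dataset`."""
    arr_path = os.path.join(path, "arrays.npz")
    if not os.path.exists(arr_path):
        raise IOError(f"no dataset archive at {path!r} (missing arrays.npz)")
    try:
        with np.load(arr_path) as z:
            images, positions, tasks = z["images"], z["positions"], z["task_labels"]
    except Exception as exc:  # corrupt archive
        raise IOError(f"could not read dataset archive at {path!r}: {exc}") from exc
    spec = None
    man_path = os.path.join(path, "manifest.yaml")
    if os.path.exists(man_path):
        with open(man_path) as fh:
            man = yaml.safe_load(fh)
        if man.get("weighting") is not None:
            spec = DatasetSpec(
                n_images=int(man["n_images"]), weighting=man["weighting"],
                seed=int(man["seed"]),
                config=CorridorConfig(sigma=float(man["sigma"]),
                                      profile=man.get("profile", "peak")),
            )
    return Dataset(images, positions, tasks, spec)

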