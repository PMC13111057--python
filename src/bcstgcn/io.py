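"""Reading and assembling DeepLabCut-style keypoint tracks.

A DLC track file has three header rows (scorer / bodyparts / coords) and one
row per frame with x, y, likelihood columns per bodypart.  Tracks are turned
into dense (C=3, T, V=17) skeleton tensors: channels are x, y and the pose
confidence, joints follow the scheme order of :mod:`bcstgcn.skeleton`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import h5py
import numpy as np
import pandas as pd

from .skeleton import KeypointScheme, build_pig_scheme

TRUNK_JOINTS = (4, 17)          # shoulder midpoint, tail root (1-based)
DEFAULT_WINDOW_T = 150          # ~6 s at 25 fps
DEFAULT_CONFIDENCE_THRESHOLD = 0.6
BEHAVIOR_CLASSES = ("feeding", "walking", "lying", "sitting")


class DLCSchemaError(ValueError):
    """Raised when a keypoint file does not match the expected DLC layout."""


@dataclass
class PoseTrack:
    """Per-frame (x, y, likelihood) records for all 17 bodyparts.

    ``coords`` has shape (T, V, 3) with the last axis (x, y, likelihood).
    """

    coords: np.ndarray
    fps: float = 25.0
    source_id: str = ""
    scheme: KeypointScheme = field(default_factory=build_pig_scheme)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[1:] != (self.scheme.n_joints, 3):
            raise ValueError(
                f"coords must have shape (T, {self.scheme.n_joints}, 3)")
        lik = self.coords[:, :, 2]
        if ((lik < 0) | (lik > 1)).any():
            raise ValueError("likelihood values must lie in [0, 1]")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]


@dataclass
class SkeletonSequence:
    """One clip as a (3, T, 17) array with channels (x, y, confidence)."""

    data: np.ndarray
    label: str | None = None
    source_id: str = ""
    normalized: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[0] != 3:
            raise ValueError("data must have shape (3, T, V)")

    @property
    def T(self) -> int:
        return self.data.shape[1]

    @property
    def V(self) -> int:
        return self.data.shape[2]


@dataclass(frozen=True)
class DatasetSplit:
    ratios: tuple[float, float, float]
    assignment: dict
    seed: int

    def items(self, part: str) -> list:
        return [k for k, v in self.assignment.items() if v == part]

    @property
    def sizes(self) -> tuple[int, int, int]:
        tags = list(self.assignment.values())
        return (tags.count("train"), tags.count("val"), tags.count("test"))


# ---------------------------------------------------------------------------
# DLC file round trip

def write_dlc_csv(track: PoseTrack, path, scorer: str = "bcstgcn") -> None:
    """Write a track in the three-header-row DLC CSV dialect."""
    names = track.scheme.names
    columns = pd.MultiIndex.from_product(
        [[scorer], names, ["x", "y", "likelihood"]],
        names=["scorer", "bodyparts", "coords"])
    T, V, _ = track.coords.shape
    df = pd.DataFrame(track.coords.reshape(T, V * 3), columns=columns)
    df.index.name = "coords"
    df.to_csv(path, float_format="%.6f")


def read_dlc_csv(path, scheme: KeypointScheme | None = None,
                 fps: float = 25.0) -> PoseTrack:
    """Read a DLC CSV; bodyparts are reordered to scheme order by name."""
    scheme = scheme or build_pig_scheme()
    try:
        df = pd.read_csv(path, header=[0, 1, 2], index_col=0)
    except (pd.errors.ParserError, IndexError) as exc:
        raise DLCSchemaError(f"{path}: not a 3-header-row DLC CSV: {exc}") from exc
    if df.columns.nlevels != 3:
        raise DLCSchemaError(f"{path}: expected 3 header rows")

    bodyparts = list(dict.fromkeys(df.columns.get_level_values(1)))
    if len(bodyparts) != scheme.n_joints:
        raise DLCSchemaError(
            f"{path}: found {len(bodyparts)} bodyparts, "
            f"expected {scheme.n_joints}")
    missing = set(scheme.names) - set(bodyparts)
    if missing:
        raise DLCSchemaError(f"{path}: missing bodyparts {sorted(missing)}")

    scorer = df.columns.get_level_values(0)[0]
    T = len(df)
    coords = np.empty((T, scheme.n_joints, 3))
    for v, name in enumerate(scheme.names):
        for c, coord in enumerate(("x", "y", "likelihood")):
            try:
                col = pd.to_numeric(df[(scorer, name, coord)], errors="raise")
            except (ValueError, KeyError) as exc:
                raise DLCSchemaError(
                    f"{path}: non-numeric or missing column "
                    f"({name}, {coord})") from exc
            coords[:, v, c] = col.to_numpy()
    if np.isnan(coords).any():
        raise DLCSchemaError(f"{path}: non-numeric cells in keypoint table")
    return PoseTrack(coords=coords, fps=fps, source_id=str(path), scheme=scheme)


def write_dlc_h5(track: PoseTrack, path) -> None:
    """Write a track as an HDF5 keypoint table (dataset + bodypart names)."""
    with h5py.File(path, "w") as fh:
        ds = fh.create_dataset("keypoints", data=track.coords)
        ds.attrs["bodyparts"] = list(track.scheme.names)
        ds.attrs["coords"] = ["x", "y", "likelihood"]
        ds.attrs["fps"] = track.fps


def read_dlc_h5(path, scheme: KeypointScheme | None = None) -> PoseTrack:
    scheme = scheme or build_pig_scheme()
    with h5py.File(path, "r") as fh:
        ds = fh["keypoints"]
        names = [n.decode() if isinstance(n, bytes) else str(n)
                 for n in ds.attrs["bodyparts"]]
        coords = ds[()]
        fps = float(ds.attrs.get("fps", 25.0))
    if len(names) != scheme.n_joints:
        raise DLCSchemaError(
            f"{path}: found {len(names)} bodyparts, expected {scheme.n_joints}")
    order = [names.index(n) for n in scheme.names]
    return PoseTrack(coords=coords[:, order, :], fps=fps,
                     source_id=str(path), scheme=scheme)


def read_label_manifest(path) -> dict[str, str]:
    """Two-column TSV (clip_id, label) -> dict."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            clip_id, label = line.split("\t")
            out[clip_id] = label
    return out


def write_label_manifest(labels: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for clip_id in labels:
            fh.write(f"{clip_id}\t{labels[clip_id]}\n")


# ---------------------------------------------------------------------------
# Track -> tensor pipeline

def _trunk_center(coords: np.ndarray) -> np.ndarray:
    """Per-frame midpoint of the trunk joints, shape (T, 2)."""
    i, j = TRUNK_JOINTS[0] - 1, TRUNK_JOINTS[1] - 1
    return 0.5 * (coords[:, i, :2] + coords[:, j, :2])


def filter_by_confidence(track: PoseTrack,
                         threshold: float = DEFAULT_CONFIDENCE_THRESHOLD) -> PoseTrack:
    """Mask keypoints whose likelihood falls below ``threshold``.

    Masked keypoints get the per-frame trunk-center coordinates (a neutral
    imputation that invents no motion) and confidence 0.  The default 0.6
    matches the pose-estimation reliability cutoff used upstream.
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must lie in [0, 1]")
    coords = track.coords.copy()
    center = _trunk_center(coords)
    low = coords[:, :, 2] < threshold
    t_idx, v_idx = np.nonzero(low)
    coords[t_idx, v_idx, 0] = center[t_idx, 0]
    coords[t_idx, v_idx, 1] = center[t_idx, 1]
    coords[t_idx, v_idx, 2] = 0.0
    return replace(track, coords=coords)


def assemble_sequence(track: PoseTrack, window_T: int = DEFAULT_WINDOW_T,
                      label: str | None = None) -> SkeletonSequence:
    """Resample a track to a fixed window and lay it out as (3, T, V).

    Shorter tracks are loop-padded; longer tracks are uniformly subsampled at
    indices round(i * L / window_T).
    """
    if window_T < 1:
        raise ValueError("window_T must be >= 1")
    L = track.n_frames
    if L == 0:
        raise ValueError("cannot assemble an empty track")
    if L == window_T:
        frames = track.coords
    elif L < window_T:
        idx = np.arange(window_T) % L
        frames = track.coords[idx]
    else:
        idx = np.minimum(np.round(np.arange(window_T) * L / window_T).astype(int),
                         L - 1)
        frames = track.coords[idx]
    data = np.transpose(frames, (2, 0, 1))  # (3, T, V)
    return SkeletonSequence(data=data.copy(), label=label,
                            source_id=track.source_id)


def normalize_coordinates(seq: SkeletonSequence) -> SkeletonSequence:
    """Trunk-center every frame and scale so the median trunk length is 1.

    Translation is per frame (midpoint of shoulder midpoint and tail root to
    the origin); scale is global per clip.  The confidence channel is
    untouched, so the transform is idempotent and invariant to rigid
    translation and uniform scaling of the input.
    """
    data = seq.data.copy()
    i, j = TRUNK_JOINTS[0] - 1, TRUNK_JOINTS[1] - 1
    cx = 0.5 * (data[0, :, i] + data[0, :, j])
    cy = 0.5 * (data[1, :, i] + data[1, :, j])
    trunk_len = np.hypot(data[0, :, i] - data[0, :, j],
                         data[1, :, i] - data[1, :, j])
    positive = trunk_len[trunk_len > 0]
    if positive.size == 0:
        raise ValueError("trunk length is zero in every frame; cannot scale")
    scale = float(np.median(positive))
    data[0] = (data[0] - cx[:, None]) / scale
    data[1] = (data[1] - cy[:, None]) / scale
    return SkeletonSequence(data=data, label=seq.label,
                            source_id=seq.source_id, normalized=True)


# ---------------------------------------------------------------------------
# Dataset split

def largest_remainder(n: int, ratios) -> tuple[int, ...]:
    """Apportion n items to len(ratios) parts by the largest-remainder rule."""
    ratios = np.asarray(ratios, dtype=float)
    quota = n * ratios / ratios.sum()
    base = np.floor(quota).astype(int)
    rem = quota - base
    short = n - base.sum()
    # ties broken toward the earlier part for determinism
    order = np.argsort(-rem, kind="stable")
    for k in order[:short]:
        base[k] += 1
    return tuple(int(b) for b in base)


def split_dataset(item_ids, ratios=(7, 2, 1), seed: int = 0,
                  labels: dict | None = None,
                  stratified: bool = False) -> DatasetSplit:
    """7:2:1 train/val/test split by seeded permutation.

    Sizes follow the largest-remainder apportionment; the assignment is a
    deterministic function of the sorted item ids and the seed, so it is
    stable under permutation of the input order.  Stratified mode applies the
    same rule within each label group.
    """
    item_ids = list(item_ids)
    if not item_ids:
        raise ValueError("item list is empty")
    if stratified and labels is None:
        raise ValueError("stratified split requires labels")

    def _assign(ids, rng):
        ids = sorted(ids, key=str)
        perm = rng.permutation(len(ids))
        shuffled = [ids[p] for p in perm]
        n_train, n_val, n_test = largest_remainder(len(ids), ratios)
        out = {}
        for k, item in enumerate(shuffled):
            if k < n_train:
                out[item] = "train"
            elif k < n_train + n_val:
                out[item] = "val"
            else:
                out[item] = "test"
        return out

    rng = np.random.default_rng(seed)
    assignment: dict = {}
    if stratified:
        for lab in sorted({labels[i] for i in item_ids}):
            group = [i for i in item_ids if labels[i] == lab]
            assignment.update(_assign(group, rng))
    else:
        assignment = _assign(item_ids, rng)
    return DatasetSplit(ratios=tuple(ratios), assignment=assignment, seed=seed)


def write_split_manifest(split: DatasetSplit, path) -> None:
    """Three-column TSV: clip_id, partition, seed."""
    with open(path, "w") as fh:
        for item, part in split.assignment.items():
            fh.write(f"{item}\t{part}\t{split.seed}\n")


# ---------------------------------------------------------------------------
# Augmentation

@dataclass(frozen=True)
class AugmentParams:
    """Strengths of the four augmentation operators.

    Coordinates are in the units of the input tensors (pixels for raw tracks);
    callers augmenting normalized sequences should pass scaled-down values.
    """

    occlusion_block: int = 12       # frames per occlusion window
    occlusion_joints: int = 2       # joints occluded per event
    erasure_joints: int = 1         # whole joints masked
    drift_amp: float = 10.0         # background-disturbance amplitude
    drift_freq: float = 0.3         # Hz, low-frequency coherent drift
    noise_sigma: float = 2.0        # Gaussian coordinate noise


ALL_AUGMENT_OPS = ("random_occlusion", "joint_erasure",
                   "background_disturbance", "gaussian_noise")


def augment(seq: SkeletonSequence, ops=ALL_AUGMENT_OPS,
            params: AugmentParams = AugmentParams(),
            seed: int = 0, fps: float = 25.0) -> SkeletonSequence:
    """Apply the selected augmentation operators; topology is untouched.

    The joint ordering, edge structure, array shape and label never change:
    occlusion and erasure only zero confidences, disturbance and noise only
    perturb coordinates.  Deterministic for a fixed seed.
    """
    if params.noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    rng = np.random.default_rng(seed)
    data = seq.data.copy()
    C, T, V = data.shape

    if "random_occlusion" in ops:
        joints = rng.choice(V, size=min(params.occlusion_joints, V),
                            replace=False)
        block = min(params.occlusion_block, T)
        start = int(rng.integers(0, T - block + 1))
        data[2, start:start + block][:, joints] = 0.0
    if "joint_erasure" in ops:
        joints = rng.choice(V, size=min(params.erasure_joints, V),
                            replace=False)
        data[2, :, joints] = 0.0
    if "background_disturbance" in ops:
        t = np.arange(T) / fps
        for ch in (0, 1):
            amp = params.drift_amp * rng.uniform(0.5, 1.0)
            phase = rng.uniform(0, 2 * np.pi)
            drift = amp * np.sin(2 * np.pi * params.drift_freq * t + phase)
            data[ch] += drift[:, None]
    if "gaussian_noise" in ops and params.noise_sigma > 0:
        data[:2] += rng.normal(0.0, params.noise_sigma, size=(2, T, V))

    return SkeletonSequence(data=data, label=seq.label,
                            source_id=seq.source_id, normalized=seq.normalized)


def erase_joint(seq: SkeletonSequence, joint: int) -> SkeletonSequence:
    """Mask one 1-based joint (confidence channel zeroed in every frame)."""
    data = seq.data.copy()
    data[2, :, joint - 1] = 0.0
    return SkeletonSequence(data=data, label=seq.label,
                            source_id=seq.source_id, normalized=seq.normalized)


def expand_dataset(seqs, factor: int = 3, seed: int = 0,
                   ops=ALL_AUGMENT_OPS,
                   params: AugmentParams = AugmentParams()):
    """Expand a sequence list ``factor``-fold by augmentation.

    The first copy of every item is the unmodified original; the remaining
    factor-1 copies are augmented variants with per-copy derived seeds.  The
    default factor 3 triples the corpus.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    out = []
    for i, seq in enumerate(seqs):
        out.append(seq)
        for rep in range(1, factor):
            child = np.random.SeedSequence(seed, spawn_key=(i, rep))
            sub_seed = int(child.generate_state(1)[0] % (2 ** 31))
            out.append(augment(seq, ops=ops, params=params, seed=sub_seed))
    return out
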