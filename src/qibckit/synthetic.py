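"""Synthetic ground-truth data: nuclei scenes, rendered fields, DNA sequences.

Scenes model an asynchronous interphase population: G1 cells carry 2C DNA
content, G2 cells 4C, S-phase cells a uniform draw in (2, 4). Nuclei are
rendered as filled disks; the DAPI channel encodes DNA content through the
*integrated* intensity over the disk (pixel value = dapi_per_c x content /
disk area), so the noiseless integral is exact by construction. Marker
channels are flat at the nucleus' true mean inside the disk. Everything is a
pure function of (config, seed).

The DNA-sequence helpers (:func:`random_sequence`, :func:`plant_motifs`)
provide controlled substrates for motif-counting tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from skimage.draw import disk as draw_disk

from .errors import PlacementError, ValidationError
from .images import ChannelImage, FieldOfView, LabelMask
from .presets import BASE_CHANNEL_MEANS, DEFAULT_CHANNELS, PHASES, ConditionPreset, get_preset

#: minimum clearance (pixels) between non-partner nucleus boundaries
_ISOLATION_MARGIN = 6.0
#: centre distance of a planted touching pair, as a fraction of r1+r2;
#: guarantees one fused binary component for watershed testing
TOUCHING_DISTANCE_FACTOR = 0.8
_MAX_ATTEMPTS_PER_NUCLEUS = 2000


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of one synthetic field of nuclei.

    ``fraction_g1 + fraction_s + fraction_g2`` must equal 1.
    ``dapi_per_c`` is the integrated DAPI intensity corresponding to 1C of
    DNA content. ``touching_pair_fraction`` is the fraction of nuclei placed
    as members of a deliberately fused pair. ``intensity_cv`` is the
    log-normal sigma of cell-to-cell variation applied to marker means.
    Background level, dynamic range and noise defaults are arbitrary
    (unconstrained by any acquisition metadata) and freely configurable.
    """

    field_shape: tuple[int, int] = (1024, 1024)
    n_nuclei: int = 100
    radius_range: tuple[float, float] = (10.0, 16.0)
    fraction_g1: float = 0.5
    fraction_s: float = 0.3
    fraction_g2: float = 0.2
    dapi_per_c: float = 1_000_000.0
    touching_pair_fraction: float = 0.0
    background_level: float = 100.0
    noise_sd: float = 0.0
    condition: str = "untreated"
    seed: int = 0
    channels: tuple[str, ...] = DEFAULT_CHANNELS
    intensity_cv: float = 0.15

    def __post_init__(self) -> None:
        total = self.fraction_g1 + self.fraction_s + self.fraction_g2
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"phase fractions sum to {total}, expected 1")
        if min(self.fraction_g1, self.fraction_s, self.fraction_g2) < 0:
            raise ValidationError("phase fractions must be non-negative")
        if self.n_nuclei < 0:
            raise ValidationError("n_nuclei must be >= 0")
        rmin, rmax = self.radius_range
        if not (0 < rmin <= rmax):
            raise ValidationError(f"invalid radius_range {self.radius_range}")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if not (0.0 <= self.touching_pair_fraction <= 1.0):
            raise ValidationError("touching_pair_fraction must be in [0, 1]")
        if "DAPI" not in self.channels:
            raise ValidationError("channels must include 'DAPI'")
        get_preset(self.condition)  # raises on unknown preset


@dataclass(frozen=True)
class GroundTruthNucleus:
    """One simulated nucleus with known state.

    ``true_channel_means`` covers the marker channels (not DAPI, whose ground
    truth is the integrated intensity ``dapi_per_c * dna_content``).
    """

    id: int
    center: tuple[float, float]
    radius: float
    phase: str
    dna_content: float
    true_channel_means: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.id < 1:
            raise ValidationError("nucleus id must be a positive integer")
        if self.radius <= 0:
            raise ValidationError("radius must be > 0")
        if self.phase not in PHASES:
            raise ValidationError(f"unknown phase {self.phase!r}")
        expected = {"G1": (2.0, 2.0), "S": (2.0, 4.0), "G2": (4.0, 4.0)}[self.phase]
        if not (expected[0] <= self.dna_content <= expected[1]):
            raise ValidationError(
                f"dna_content {self.dna_content} inconsistent with phase {self.phase}"
            )


@dataclass(frozen=True)
class SyntheticScene:
    """Ground truth for one field: config, nuclei and planted touching pairs."""

    config: SceneConfig
    nuclei: tuple[GroundTruthNucleus, ...]
    touching_pairs: tuple[tuple[int, int], ...] = ()

    @property
    def channel_names(self) -> tuple[str, ...]:
        return self.config.channels

    def nucleus(self, nucleus_id: int) -> GroundTruthNucleus:
        return self.nuclei[nucleus_id - 1]


def _draw_phases(rng: np.random.Generator, config: SceneConfig) -> np.ndarray:
    probs = [config.fraction_g1, config.fraction_s, config.fraction_g2]
    return rng.choice(np.array(PHASES), size=config.n_nuclei, p=probs)


def _place_centres(
    rng: np.random.Generator, config: SceneConfig, radii: np.ndarray
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Rejection-sample centres: fused pairs first, then isolated nuclei."""
    n = config.n_nuclei
    rows, cols = config.field_shape
    centres = np.zeros((n, 2), dtype=float)
    placed: list[int] = []
    pairs: list[tuple[int, int]] = []

    n_paired = int(round(config.touching_pair_fraction * n))
    n_pairs = n_paired // 2

    def fits(i: int, r0: float, c0: float, partner_of: int | None = None) -> bool:
        margin = radii[i] + 2.0
        if not (margin <= r0 <= rows - 1 - margin and margin <= c0 <= cols - 1 - margin):
            return False
        for j in placed:
            if j == partner_of:
                continue
            d = math.hypot(r0 - centres[j, 0], c0 - centres[j, 1])
            if d < radii[i] + radii[j] + _ISOLATION_MARGIN:
                return False
        return True

    def place_isolated(i: int) -> None:
        for _ in range(_MAX_ATTEMPTS_PER_NUCLEUS):
            r0 = rng.uniform(0, rows - 1)
            c0 = rng.uniform(0, cols - 1)
            if fits(i, r0, c0):
                centres[i] = (r0, c0)
                placed.append(i)
                return
        raise PlacementError(
            f"could not place nucleus {i + 1} of {n} in field {config.field_shape}"
        )

    for k in range(n_pairs):
        anchor, partner = 2 * k, 2 * k + 1
        place_isolated(anchor)
        dist = TOUCHING_DISTANCE_FACTOR * (radii[anchor] + radii[partner])
        for _ in range(_MAX_ATTEMPTS_PER_NUCLEUS):
            theta = rng.uniform(0.0, 2.0 * math.pi)
            r0 = centres[anchor, 0] + dist * math.sin(theta)
            c0 = centres[anchor, 1] + dist * math.cos(theta)
            if fits(partner, r0, c0, partner_of=anchor):
                centres[partner] = (r0, c0)
                placed.append(partner)
                break
        else:
            raise PlacementError(
                f"could not place touching partner for nucleus {anchor + 1}"
            )
        pairs.append((anchor + 1, partner + 1))

    for i in range(2 * n_pairs, n):
        place_isolated(i)

    return centres, pairs


def make_scene(config: SceneConfig) -> SyntheticScene:
    """Generate the ground truth for one field.

    Deterministic given ``config`` (which includes the seed). Raises
    :class:`PlacementError` when the field cannot accommodate ``n_nuclei``
    within the attempt cap.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_nuclei
    if n == 0:
        return SyntheticScene(config=config, nuclei=())

    phases = _draw_phases(rng, config)
    dna = np.where(phases == "G1", 2.0, np.where(phases == "G2", 4.0, 0.0))
    s_mask = phases == "S"
    dna[s_mask] = rng.uniform(2.0, 4.0, size=int(s_mask.sum()))
    rmin, rmax = config.radius_range
    radii = rng.uniform(rmin, rmax, size=n)

    preset = get_preset(config.condition)
    marker_channels = [ch for ch in config.channels if ch != "DAPI"]
    means = np.zeros((n, len(marker_channels)))
    for i in range(n):
        for j, ch in enumerate(marker_channels):
            base = BASE_CHANNEL_MEANS.get(ch, {"G1": 20.0, "S": 20.0, "G2": 20.0})
            mu = preset.mean(ch, phases[i], base[phases[i]])
            if config.intensity_cv > 0:
                mu *= rng.lognormal(0.0, config.intensity_cv)
            means[i, j] = mu

    centres, pairs = _place_centres(rng, config, radii)

    nuclei = tuple(
        GroundTruthNucleus(
            id=i + 1,
            center=(float(centres[i, 0]), float(centres[i, 1])),
            radius=float(radii[i]),
            phase=str(phases[i]),
            dna_content=float(dna[i]),
            true_channel_means={ch: float(means[i, j]) for j, ch in enumerate(marker_channels)},
        )
        for i in range(n)
    )
    return SyntheticScene(config=config, nuclei=nuclei, touching_pairs=tuple(pairs))


def _disk_coords(
    nucleus: GroundTruthNucleus, shape: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    return draw_disk(nucleus.center, nucleus.radius, shape=shape)


def render_scene(scene: SyntheticScene, noise_seed: int | None = None) -> FieldOfView:
    """Render a scene to one float image per channel.

    DAPI inside each nucleus is ``dapi_per_c * dna_content / area`` so the
    noiseless integral over the rasterised disk equals
    ``dapi_per_c * dna_content`` exactly; marker channels are flat at the
    nucleus' true mean. Contributions add where planted pairs overlap.
    Background is added everywhere, Gaussian noise when ``noise_sd > 0``
    (seeded from the scene unless ``noise_seed`` is given), and values are
    clipped to the non-negative 16-bit range.
    """
    config = scene.config
    shape = config.field_shape
    images = {ch: np.full(shape, float(config.background_level)) for ch in scene.channel_names}

    for nucleus in scene.nuclei:
        rr, cc = _disk_coords(nucleus, shape)
        area = rr.size
        if area == 0:
            continue
        images["DAPI"][rr, cc] += config.dapi_per_c * nucleus.dna_content / area
        for ch, mu in nucleus.true_channel_means.items():
            images[ch][rr, cc] += mu

    if config.noise_sd > 0:
        seed = config.seed if noise_seed is None else noise_seed
        noise_rng = np.random.default_rng(np.random.SeedSequence([seed, 0xA5]))
        for ch in scene.channel_names:
            images[ch] += noise_rng.normal(0.0, config.noise_sd, size=shape)

    max_value = float(2**16 - 1)
    channels = {
        ch: ChannelImage(np.clip(img, 0.0, max_value), ch, bit_depth=16)
        for ch, img in images.items()
    }
    return FieldOfView(channels=channels, field_id=f"scene-{config.seed}")


def ground_truth_mask(scene: SyntheticScene) -> LabelMask:
    """Rasterise the true disks into a label mask (later ids win on overlap)."""
    labels = np.zeros(scene.config.field_shape, dtype=np.int32)
    for nucleus in scene.nuclei:
        rr, cc = _disk_coords(nucleus, scene.config.field_shape)
        labels[rr, cc] = nucleus.id
    return LabelMask.from_labels(labels)


def match_to_ground_truth(scene: SyntheticScene, mask: LabelMask) -> list[dict]:
    """Score a segmentation against the scene's true disks.

    For each ground-truth nucleus, finds the predicted label with the largest
    pixel overlap with the true disk and reports the IoU. Returns one dict
    per nucleus: ``{"id", "matched_label", "iou"}`` (``matched_label`` 0 and
    IoU 0 when nothing overlaps).
    """
    pred_areas = mask.areas()
    out = []
    for nucleus in scene.nuclei:
        rr, cc = _disk_coords(nucleus, scene.config.field_shape)
        under = mask.labels[rr, cc]
        counts = np.bincount(under, minlength=mask.n_objects + 1)
        counts[0] = 0
        best = int(counts.argmax())
        if best == 0 or counts[best] == 0:
            out.append({"id": nucleus.id, "matched_label": 0, "iou": 0.0})
            continue
        inter = int(counts[best])
        union = rr.size + int(pred_areas[best]) - inter
        out.append({"id": nucleus.id, "matched_label": best, "iou": inter / union})
    return out


# ---------------------------------------------------------------------------
# DNA sequence generators
# ---------------------------------------------------------------------------

_DNA_BASES = ("A", "C", "G", "T")


def random_sequence(length: int, base_probs: Mapping[str, float], seed: int) -> str:
    """Draw an i.i.d. DNA string over {A, C, G, T}.

    ``base_probs`` maps bases to probabilities summing to 1 (missing bases
    get probability 0). Deterministic given ``seed``.
    """
    if length < 0:
        raise ValidationError("length must be >= 0")
    unknown = set(base_probs) - set(_DNA_BASES)
    if unknown:
        raise ValidationError(f"unknown bases in base_probs: {sorted(unknown)}")
    probs = np.array([float(base_probs.get(b, 0.0)) for b in _DNA_BASES])
    if probs.min() < 0:
        raise ValidationError("base probabilities must be non-negative")
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValidationError(f"base probabilities sum to {probs.sum()}, expected 1")
    if length == 0:
        return ""
    rng = np.random.default_rng(seed)
    letters = np.frombuffer(b"ACGT", dtype="S1")
    draws = rng.choice(letters, size=length, p=probs / probs.sum())
    return draws.tobytes().decode("ascii")


def plant_motifs(sequence: str, motif: str, positions: Sequence[int]) -> str:
    """Overwrite ``motif`` into ``sequence`` at each 0-based offset, in order.

    Later plants overwrite earlier ones where they overlap. Raises
    :class:`ValidationError` on out-of-range positions.
    """
    if not motif:
        raise ValidationError("motif must be non-empty")
    buf = bytearray(sequence.encode("ascii"))
    m = motif.encode("ascii")
    for pos in positions:
        if pos < 0 or pos + len(m) > len(buf):
            raise ValidationError(
                f"plant position {pos} out of range for motif length {len(m)} "
                f"in sequence length {len(buf)}"
            )
        buf[pos : pos + len(m)] = m
    return buf.decode("ascii")
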