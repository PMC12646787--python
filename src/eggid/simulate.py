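"""Simulated brood parasitism and synthetic data generation.

Two layers of synthesis:

* trait level — clutches drawn from a hierarchical Gaussian (female mean
  vectors with between-female spread larger than within-female spread, the
  structure real swallow clutches show), with optional deviant first/last
  laid eggs;
* image level — rendered prolate spotted eggs with controllable spot
  density and size, per-channel reflectances and uneven illumination, plus
  a ground-truth spot mask for segmentation oracles.

Plus the parasitism bookkeeping: exhaustive enumeration of (host clutch,
foreign egg) combinations and per-participant assessment-set sampling in the
two game layouts (game 1: pick the odd egg among six; game 2: four known
host eggs and two candidates).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

from .imaging import CalibratedEggImage
from .traits import TRAIT_COLUMNS

# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class Clutch:
    """Eggs of one female, in laying order where known."""

    clutch_id: str
    eggs: list[str]

    def __post_init__(self) -> None:
        if len(set(self.eggs)) != len(self.eggs):
            raise ValueError("duplicate egg ids in clutch")


@dataclass
class ParasitizedClutch:
    """A five-egg host clutch plus one foreign egg, with both game layouts.

    Game 1 presents all six eggs interchangeably; game 2 partitions them
    into four known host eggs (laid in regular daily sequence) and two
    candidates — the remaining host egg and the parasite.
    """

    clutch_id: str
    host_eggs: list[str]  # 5 ids
    parasite_egg: str
    parasite_clutch: str
    known_hosts: list[str] = field(default_factory=list)  # 4 of host_eggs
    candidates: list[str] = field(default_factory=list)  # [5th host, parasite]
    display_order: list[str] = field(default_factory=list)  # permutation of 6

    def __post_init__(self) -> None:
        if self.parasite_clutch == self.clutch_id:
            raise ValueError("parasite must come from a different female")
        if self.parasite_egg in self.host_eggs:
            raise ValueError("parasite egg cannot be a host egg")
        if self.known_hosts:
            if len(self.known_hosts) != 4 or not set(self.known_hosts) <= set(
                self.host_eggs
            ):
                raise ValueError("known_hosts must be 4 host eggs")
            expect = set(self.host_eggs) - set(self.known_hosts) | {self.parasite_egg}
            if set(self.candidates) != expect:
                raise ValueError("candidates must be the 5th host egg + parasite")
        if not self.display_order:
            self.display_order = self.host_eggs + [self.parasite_egg]

    @property
    def all_eggs(self) -> list[str]:
        return self.host_eggs + [self.parasite_egg]


@dataclass
class SynthConfig:
    """Parameters of the trait-level generator.

    The defaults mirror the study conditions: 54 females with five-egg
    clutches and scaled-trait spreads sigma_between = 0.82 and
    sigma_within = 0.58 (the within/between variance metrics reported for
    real swallow clutches; note 0.82^2 + 0.58^2 ~ 1, consistent with traits
    z-scored over the full egg set).
    """

    n_females: int = 54
    eggs_per_clutch: int = 5
    sigma_between: float = 0.82
    sigma_within: float = 0.58
    last_egg_shift: float | np.ndarray = 0.0
    first_egg_shift: float | np.ndarray = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_between < 0 or self.sigma_within < 0:
            raise ValueError("sigmas must be nonnegative")
        if self.n_females < 2:
            raise ValueError("need at least 2 females")


@dataclass
class ImageSynthConfig:
    """Parameters of the image-level egg renderer (units: mm and reflectance)."""

    length_mm: float = 19.0
    width_mm: float = 13.5
    scale: float = 15.0  # px per mm
    background: dict[str, float] = field(
        default_factory=lambda: {"R": 0.75, "G": 0.70, "B": 0.65, "UV": 0.35, "LUM": 0.70}
    )
    spot: dict[str, float] = field(
        default_factory=lambda: {"R": 0.35, "G": 0.25, "B": 0.22, "UV": 0.12, "LUM": 0.25}
    )
    n_spots: int = 40
    spot_radius_mm: float = 0.35
    spot_radius_sd_mm: float = 0.08
    min_separation_mm: float = 0.0
    zone_weights: tuple[float, float, float] = (1.0, 1.0, 1.0)  # blunt/middle/sharp
    gradient_amplitude: float = 0.0
    margin_px: int = 12
    seed: int = 0


# ---------------------------------------------------------------------------
# Parasitism bookkeeping
# ---------------------------------------------------------------------------


def enumerate_combinations(
    clutches: list[Clutch],
) -> tuple[int, Iterator[tuple[str, str]]]:
    """All (host clutch, foreign egg) pairings.

    Every egg of every other female can parasitize every host clutch, so the
    count is sum_c (N_total_eggs - n_c); 54 five-egg clutches give
    54 x 265 = 14 310.
    """
    if len(clutches) < 2:
        raise ValueError("need at least 2 clutches")
    total = sum(len(c.eggs) for c in clutches)
    count = sum(total - len(c.eggs) for c in clutches)

    def _iter() -> Iterator[tuple[str, str]]:
        for host in clutches:
            for other in clutches:
                if other.clutch_id == host.clutch_id:
                    continue
                for egg in other.eggs:
                    yield host.clutch_id, egg

    return count, _iter()


def make_parasitized_clutch(
    host: Clutch,
    parasite_egg: str,
    parasite_clutch: str,
    rng: np.random.Generator,
) -> ParasitizedClutch:
    """Assemble both game layouts for one (host, parasite) combination."""
    known = list(rng.choice(host.eggs, size=4, replace=False))
    fifth = next(e for e in host.eggs if e not in known)
    order = list(rng.permutation(host.eggs + [parasite_egg]))
    return ParasitizedClutch(
        clutch_id=host.clutch_id,
        host_eggs=list(host.eggs),
        parasite_egg=parasite_egg,
        parasite_clutch=parasite_clutch,
        known_hosts=known,
        candidates=[fifth, parasite_egg],
        display_order=order,
    )


def sample_assessment_sets(
    clutches: list[Clutch],
    n_participants: int = 35,
    seed: int = 0,
) -> dict[int, list[ParasitizedClutch]]:
    """One slide per host clutch per participant, parasites drawn at random.

    Each participant assesses every host clutch once with a randomly chosen
    foreign egg (duplicates across participants possible); 35 participants
    over 54 clutches yield the study's 1 890 slides.  Sets are reusable
    across games — the same layouts serve game 1 and game 2.
    """
    rng = np.random.default_rng(seed)
    egg_owner = {e: c.clutch_id for c in clutches for e in c.eggs}
    out: dict[int, list[ParasitizedClutch]] = {}
    for p in range(1, n_participants + 1):
        slides = []
        for host in clutches:
            foreign = [e for e in egg_owner if egg_owner[e] != host.clutch_id]
            egg = str(rng.choice(foreign))
            slides.append(
                make_parasitized_clutch(host, egg, egg_owner[egg], rng)
            )
        out[p] = slides
    return out


# ---------------------------------------------------------------------------
# Trait-level generator
# ---------------------------------------------------------------------------


def synth_clutches(cfg: SynthConfig) -> tuple[list[Clutch], pd.DataFrame]:
    """Hierarchical Gaussian clutches in nine-trait space.

    Female means ~ N(0, sigma_between^2 I9); eggs ~ N(mean, sigma_within^2 I9);
    optional additive shifts to the first and last laid eggs.  Deterministic
    under the config seed.
    """
    rng = np.random.default_rng(cfg.seed)
    k = cfg.eggs_per_clutch
    clutches: list[Clutch] = []
    rows = []
    for f in range(cfg.n_females):
        cid = f"F{f + 1:03d}"
        mean = rng.normal(0.0, cfg.sigma_between, size=9)
        eggs = []
        for e in range(k):
            eid = f"{cid}_E{e + 1}"
            t = rng.normal(mean, cfg.sigma_within)
            if e == 0:
                t = t + np.broadcast_to(np.asarray(cfg.first_egg_shift, float), (9,))
            if e == k - 1:
                t = t + np.broadcast_to(np.asarray(cfg.last_egg_shift, float), (9,))
            eggs.append(eid)
            row = {"egg_id": eid, "clutch_id": cid, "laying_order": e + 1}
            row.update({c: t[i] for i, c in enumerate(TRAIT_COLUMNS)})
            rows.append(row)
        clutches.append(Clutch(clutch_id=cid, eggs=eggs))
    return clutches, pd.DataFrame(rows)


def clutches_from_traits(traits: pd.DataFrame) -> list[Clutch]:
    """Recover Clutch objects from a traits table (laying order if present)."""
    out = []
    for cid, sub in traits.groupby("clutch_id", sort=False):
        if "laying_order" in sub.columns and sub["laying_order"].notna().all():
            sub = sub.sort_values("laying_order")
        out.append(Clutch(clutch_id=str(cid), eggs=[str(e) for e in sub["egg_id"]]))
    return out


# ---------------------------------------------------------------------------
# Image-level generator
# ---------------------------------------------------------------------------


def _ellipse_alpha(h: int, w: int, cx: float, cy: float, a: float, b: float) -> np.ndarray:
    """Anti-aliased inside-ellipse coverage via the normalised implicit field."""
    y, x = np.mgrid[0:h, 0:w]
    f = ((x - cx) / a) ** 2 + ((y - cy) / b) ** 2
    # approximate signed distance (px) from the level set f = 1
    gx = 2 * (x - cx) / a**2
    gy = 2 * (y - cy) / b**2
    grad = np.sqrt(gx * gx + gy * gy)
    d = (1.0 - f) / np.maximum(grad, 1e-9)
    return np.clip(d + 0.5, 0.0, 1.0)


def render_egg_image(
    cfg: ImageSynthConfig,
    egg_id: str = "synthetic",
    clutch_id: str = "synthetic",
    blunt_end: str = "left",
) -> tuple[CalibratedEggImage, np.ndarray]:
    """Render a prolate spotted egg; returns the image and ground-truth spot mask.

    Spots are anti-aliased dark disks placed by a seeded point process with
    optional per-zone density weights and minimum separation; an optional
    multiplicative left-right illumination gradient emulates uneven lighting.
    """
    rng = np.random.default_rng(cfg.seed)
    a = cfg.length_mm / 2.0 * cfg.scale  # semi-axes in px
    b = cfg.width_mm / 2.0 * cfg.scale
    if cfg.spot_radius_mm * cfg.scale >= 2 * b:
        raise ValueError("spot radius must be smaller than the egg width")
    m = cfg.margin_px
    w = int(np.ceil(2 * a)) + 2 * m
    h = int(np.ceil(2 * b)) + 2 * m
    cx, cy = w / 2.0, h / 2.0
    alpha = _ellipse_alpha(h, w, cx, cy, a, b)
    mask = alpha > 0.5

    # spot placement inside a margin-eroded ellipse
    centers: list[tuple[float, float]] = []
    radii: list[float] = []
    min_sep = cfg.min_separation_mm * cfg.scale
    zone_w = np.asarray(cfg.zone_weights, dtype=float)
    zone_p = zone_w / zone_w.sum()
    tries = 0
    while len(centers) < cfg.n_spots and tries < 200 * max(cfg.n_spots, 1):
        tries += 1
        r_spot = max(
            rng.normal(cfg.spot_radius_mm, cfg.spot_radius_sd_mm) * cfg.scale, 1.0
        )
        zone = rng.choice(3, p=zone_p)  # 0 blunt, 1 middle, 2 sharp
        x_lo = cx - a + zone * (2 * a / 3.0)
        x = rng.uniform(x_lo, x_lo + 2 * a / 3.0)
        y = rng.uniform(cy - b, cy + b)
        # keep the whole disk inside the egg
        if ((x - cx) / (a - r_spot - 1)) ** 2 + ((y - cy) / (b - r_spot - 1)) ** 2 >= 1:
            continue
        if min_sep > 0 and any(
            np.hypot(x - px, y - py) < min_sep + r_spot + pr
            for (px, py), pr in zip(centers, radii)
        ):
            continue
        centers.append((x, y))
        radii.append(r_spot)
    if cfg.n_spots and len(centers) < cfg.n_spots:
        raise ValueError("could not place all spots; relax separation/density")

    spot_cov = np.zeros((h, w))
    truth = np.zeros((h, w), dtype=bool)
    yy, xx = np.mgrid[0:h, 0:w]
    for (x, y), r_spot in zip(centers, radii):
        d = r_spot - np.hypot(xx - x, yy - y)
        cov = np.clip(d + 0.5, 0.0, 1.0)
        spot_cov = np.maximum(spot_cov, cov)
        truth |= cov > 0.5

    grad = 1.0
    if cfg.gradient_amplitude:
        grad = 1.0 + cfg.gradient_amplitude * (xx / max(w - 1, 1) - 0.5) * 2.0

    channels: dict[str, np.ndarray] = {}
    for ch in ("R", "G", "B", "UV", "LUM"):
        base = cfg.background[ch] * (1 - spot_cov) + cfg.spot[ch] * spot_cov
        img = base * alpha  # dark background outside the egg
        img = img * grad if cfg.gradient_amplitude else img
        channels[ch] = np.clip(img, 0.0, 1.0)

    egg = CalibratedEggImage(
        channels=channels,
        mask=mask,
        scale=cfg.scale,
        egg_id=egg_id,
        clutch_id=clutch_id,
        blunt_end=blunt_end,
    )
    return egg, truth
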