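"""File I/O, configuration and seed plumbing for the pipeline.

Interchange formats are plain CSV (UTF-8, '.' decimal): a sidecar metadata
table for images, one row per egg for raw features and traits, a layouts
table for parasitized clutches, and JSON for the trait model and run
summaries.  All randomness flows from one master seed; per-stage sub-seeds
derive deterministically via ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .imaging import CHANNELS, CalibratedEggImage, ImagingParams, feature_columns
from .simulate import ParasitizedClutch
from .traits import TRAIT_COLUMNS, GROUP_COMPONENTS, ImportanceWeights, TraitModel

METADATA_COLUMNS = ["egg_id", "clutch_id", "scale_px_per_mm", "blunt_end", "path"]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline, defaulting to the study conventions."""

    # imaging
    blur_radius_px: int = 2048
    phansalkar_radius_px: int = 50
    shrink_fraction: float = 0.03
    n_scales: int = 12
    # traits
    component_counts: dict = field(default_factory=lambda: dict(GROUP_COMPONENTS))
    n_trees_ranking: int = 500
    # detection
    n_same: int = 265
    n_diff: int = 265
    n_repeats: int = 10
    n_trees: int = 500
    med_threshold: float = 350.0
    # randomness
    seed: int = 0

    def imaging_params(self) -> ImagingParams:
        return ImagingParams(
            blur_radius_px=self.blur_radius_px,
            phansalkar_radius_px=self.phansalkar_radius_px,
            shrink_fraction=self.shrink_fraction,
            n_scales=self.n_scales,
        )

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage sub-seed below 2**31."""
        h = np.random.SeedSequence(
            [self.seed & 0x7FFFFFFF, abs(hash(stage)) % (2**31)]
        )
        return int(h.generate_state(1)[0] % (2**31))

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            data = yaml.safe_load(text) or {}
        else:
            data = json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        import hashlib

        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


# ---------------------------------------------------------------------------
# Image I/O
# ---------------------------------------------------------------------------


def write_egg_image(img: CalibratedEggImage, path: str | Path) -> None:
    """Write the five channels + mask as a multi-page float32 TIFF."""
    pages = [img.channels[ch].astype(np.float32) for ch in CHANNELS]
    pages.append(img.mask.astype(np.float32))
    tifffile.imwrite(str(path), np.stack(pages))


def read_egg_image(
    path: str | Path,
    egg_id: str,
    clutch_id: str,
    scale: float,
    blunt_end: str,
) -> CalibratedEggImage:
    """Read a multi-page TIFF (R, G, B, UV, LUM, mask) or per-channel PNGs.

    A path ending in ``.tif``/``.tiff`` is a six-page stack; otherwise it is
    treated as a template with ``{channel}`` substituted per channel plus a
    ``mask`` page.
    """
    path = str(path)
    if path.endswith((".tif", ".tiff")):
        stack = tifffile.imread(path)
        if stack.shape[0] != len(CHANNELS) + 1:
            raise ValueError(
                f"expected {len(CHANNELS) + 1} pages (R,G,B,UV,LUM,mask)"
            )
        channels = {ch: stack[i].astype(float) for i, ch in enumerate(CHANNELS)}
        mask = stack[-1] > 0.5
    else:
        channels = {}
        for ch in CHANNELS:
            arr = np.asarray(Image.open(path.format(channel=ch)), dtype=float)
            channels[ch] = arr / 255.0 if arr.max() > 1.5 else arr
        arr = np.asarray(Image.open(path.format(channel="mask")), dtype=float)
        mask = arr > (127 if arr.max() > 1.5 else 0.5)
    return CalibratedEggImage(
        channels=channels,
        mask=mask,
        scale=scale,
        egg_id=egg_id,
        clutch_id=clutch_id,
        blunt_end=blunt_end,
    )


def read_image_metadata(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"metadata CSV missing columns: {missing}")
    return df


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------


def write_features_csv(rows: list[dict], path: str | Path, n_scales: int = 12) -> None:
    cols = ["egg_id", "clutch_id"] + feature_columns(n_scales)
    pd.DataFrame(rows)[cols].to_csv(path, index=False)


def read_features_csv(path: str | Path, n_scales: int = 12) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in feature_columns(n_scales) if c not in df.columns]
    if missing:
        raise ValueError(f"features CSV missing columns: {missing[:5]}...")
    return df


def write_traits_csv(traits: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in ("egg_id", "clutch_id", "laying_order") if c in traits.columns]
    traits[cols + TRAIT_COLUMNS].to_csv(path, index=False)


def read_traits_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in TRAIT_COLUMNS + ["egg_id", "clutch_id"] if c not in df.columns]
    if missing:
        raise ValueError(f"traits CSV missing columns: {missing}")
    df["egg_id"] = df["egg_id"].astype(str)
    df["clutch_id"] = df["clutch_id"].astype(str)
    return df


def save_trait_model(
    model: TraitModel, path: str | Path, weights: ImportanceWeights | None = None
) -> None:
    data = {
        "groups": model.groups,
        "means": {g: v.tolist() for g, v in model.means.items()},
        "sds": {g: v.tolist() for g, v in model.sds.items()},
        "loadings": {g: v.tolist() for g, v in model.loadings.items()},
        "explained": {g: v.tolist() for g, v in model.explained.items()},
        "n_components": model.n_components,
    }
    if weights is not None:
        data["weights"] = {"w": weights.w.tolist(), "provenance": weights.provenance}
    Path(path).write_text(json.dumps(data, indent=1))


def load_trait_model(
    path: str | Path,
) -> tuple[TraitModel, ImportanceWeights | None]:
    data = json.loads(Path(path).read_text())
    model = TraitModel(
        groups=data["groups"],
        means={g: np.asarray(v) for g, v in data["means"].items()},
        sds={g: np.asarray(v) for g, v in data["sds"].items()},
        loadings={g: np.asarray(v) for g, v in data["loadings"].items()},
        explained={g: np.asarray(v) for g, v in data["explained"].items()},
        n_components=data["n_components"],
    )
    weights = None
    if "weights" in data:
        weights = ImportanceWeights(
            w=np.asarray(data["weights"]["w"]),
            provenance=data["weights"]["provenance"],
        )
    return model, weights


def write_layouts_csv(
    layouts: list[ParasitizedClutch], path: str | Path
) -> None:
    rows = []
    for i, pc in enumerate(layouts):
        rows.append(
            {
                "layout_id": i,
                "clutch_id": pc.clutch_id,
                "host_eggs": ";".join(pc.host_eggs),
                "parasite_egg": pc.parasite_egg,
                "parasite_clutch": pc.parasite_clutch,
                "known_hosts": ";".join(pc.known_hosts),
                "candidates": ";".join(pc.candidates),
                "display_order": ";".join(pc.display_order),
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_layouts_csv(path: str | Path) -> list[ParasitizedClutch]:
    df = pd.read_csv(path)
    out = []
    for _, r in df.iterrows():
        out.append(
            ParasitizedClutch(
                clutch_id=str(r["clutch_id"]),
                host_eggs=str(r["host_eggs"]).split(";"),
                parasite_egg=str(r["parasite_egg"]),
                parasite_clutch=str(r["parasite_clutch"]),
                known_hosts=str(r["known_hosts"]).split(";"),
                candidates=str(r["candidates"]).split(";"),
                display_order=str(r["display_order"]).split(";"),
            )
        )
    return out
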