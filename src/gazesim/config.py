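"""Run configuration: structured-text (JSON) parsing, defaults, seeding.

A run configuration bundles everything a command needs: the scene (a path
to a scene JSON, or the literal string ``"demo"`` for the built-in
three-room world), the viewpoint, light and imaging blocks, the
oculomotor plant block, the planner block, a seed and an output
directory.  Every default that gets applied is recorded so the run
manifest can list them.

The single global seed fans out into named substreams (one per noise
consumer) derived from a hash of the consumer's name, so adding a new
consumer never perturbs the streams of existing ones.
"""

from __future__ import annotations

import hashlib
import json
import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Union

import numpy as np

from .oculomotor import PlantParams
from .planner import Policy, RenderContext
from .render import Lesion, LightSource
from .scene import RoomLibrary, build_demo_library, read_scene
from .viewpoint import (
    DEFAULT_BASELINE,
    EyeDirection,
    HeadPose,
    RetinalArray,
    build_retinal_array,
)

__all__ = [
    "RunConfig",
    "RunConfigError",
    "load_run_config",
    "seed_streams",
    "config_digest",
]


class RunConfigError(ValueError):
    """Malformed or unreadable run configuration."""


def seed_streams(seed: Optional[int], *names: str
                 ) -> Dict[str, Optional[np.random.Generator]]:
    """Named, independent random substreams derived from one global seed.

    Streams are keyed by name via a CRC32 of the name mixed into the seed
    sequence, so the mapping is stable across runs and insensitive to the
    set of other consumers.  With ``seed=None`` every stream is ``None``
    (the noiseless convention throughout the package).
    """
    if seed is None:
        return {name: None for name in names}
    return {
        name: np.random.default_rng(
            np.random.SeedSequence([int(seed) % (2 ** 31), zlib.crc32(name.encode())])
        )
        for name in names
    }


def config_digest(raw_text: str) -> str:
    return hashlib.sha256(raw_text.encode()).hexdigest()


@dataclass
class RunConfig:
    """Parsed run configuration plus a record of applied defaults."""

    library: RoomLibrary
    scene_source: str
    room_label: Optional[str]
    pose: HeadPose
    eyes: EyeDirection
    baseline: float
    light: LightSource
    array: RetinalArray
    sigma_freq: Optional[float]
    resolution: int
    lesion: Lesion
    plant: PlantParams
    phi: tuple
    dt: float
    duration: float
    policies: List[Policy]
    belief: Optional[np.ndarray]
    cluster_tol: float
    seed: Optional[int]
    outdir: Path
    digest: str
    defaults_applied: Dict[str, object] = field(default_factory=dict)

    def render_context(self) -> RenderContext:
        return RenderContext(
            array=self.array,
            light=self.light,
            baseline=self.baseline,
            sigma_freq=self.sigma_freq,
            resolution=self.resolution,
        )


def _get(block: dict, key: str, default, defaults: dict, path: str):
    if key in block:
        return block[key]
    defaults[f"{path}.{key}"] = default
    return default


def _parse_policies(block: list, default_place, defaults) -> List[Policy]:
    policies = []
    for i, entry in enumerate(block):
        path = f"planner.policies[{i}]"
        try:
            label = entry["label"]
            head = entry["head"]
        except (KeyError, TypeError) as exc:
            raise RunConfigError(f"{path}: missing field {exc}")
        place = _get(entry, "place", list(default_place), defaults, path)
        ego = _get(entry, "eyes", [0.0, 0.0], defaults, path)
        omega = _get(entry, "convergence", 0.0, defaults, path)
        policies.append(
            Policy(
                label=label,
                pose=HeadPose(place=tuple(place), head_dir=tuple(head)),
                eyes=EyeDirection(ego_dir=tuple(ego), convergence=omega),
            )
        )
    return policies


def load_run_config(path: Union[str, Path], base_dir: Optional[Path] = None) -> RunConfig:
    """Load and validate a JSON run configuration.

    Relative scene paths resolve against the config file's directory.
    Referenced paths must exist at load time.
    """
    path = Path(path)
    try:
        raw = path.read_text()
    except OSError as exc:
        raise RunConfigError(f"cannot read config {path}: {exc}")
    try:
        data = json.loads(raw)
    except json.JSONDecodeError as exc:
        raise RunConfigError(f"{path}: line {exc.lineno} col {exc.colno}: {exc.msg}")
    if not isinstance(data, dict):
        raise RunConfigError(f"{path}: top level must be a JSON object")

    base = base_dir if base_dir is not None else path.parent
    defaults: Dict[str, object] = {}

    scene_source = _get(data, "scene", "demo", defaults, "$")
    if scene_source == "demo":
        library = build_demo_library()
    else:
        scene_path = Path(scene_source)
        if not scene_path.is_absolute():
            scene_path = base / scene_path
        if not scene_path.exists():
            raise RunConfigError(f"scene file does not exist: {scene_path}")
        library = read_scene(scene_path)

    vp = _get(data, "viewpoint", {}, defaults, "$")
    place = _get(vp, "place", [0.0, 0.0, 1.2], defaults, "viewpoint")
    head = _get(vp, "head", [-math.pi / 4, 0.0], defaults, "viewpoint")
    ego = _get(vp, "eyes", [0.0, 0.0], defaults, "viewpoint")
    omega = _get(vp, "convergence", 0.0, defaults, "viewpoint")
    baseline = _get(vp, "baseline", DEFAULT_BASELINE, defaults, "viewpoint")
    try:
        pose = HeadPose(place=tuple(place), head_dir=tuple(head))
        eyes = EyeDirection(ego_dir=tuple(ego), convergence=omega)
    except (TypeError, ValueError) as exc:
        raise RunConfigError(f"viewpoint: {exc}")

    lb = _get(data, "light", {}, defaults, "$")
    try:
        light = LightSource(
            direction=tuple(_get(lb, "direction", [0.2, -0.2, 0.95], defaults, "light")),
            ambient=_get(lb, "ambient", 0.1, defaults, "light"),
            diffuse_coeff=_get(lb, "diffuse", 0.6, defaults, "light"),
            specular_coeff=_get(lb, "specular", 0.3, defaults, "light"),
            specular_exponent=_get(lb, "exponent", 8.0, defaults, "light"),
        )
    except (TypeError, ValueError) as exc:
        raise RunConfigError(f"light: {exc}")

    im = _get(data, "imaging", {}, defaults, "$")
    n_rows = _get(im, "n_rows", 32, defaults, "imaging")
    n_cols = _get(im, "n_cols", 32, defaults, "imaging")
    extent = math.radians(_get(im, "extent_deg", 40.0, defaults, "imaging"))
    sigma_freq = _get(im, "sigma_freq", None, defaults, "imaging")
    resolution = _get(im, "resolution", 8, defaults, "imaging")
    try:
        array = build_retinal_array(n_rows, n_cols, extent)
    except (TypeError, ValueError) as exc:
        raise RunConfigError(f"imaging: {exc}")

    lz = _get(data, "lesion", {"mode": "none"}, defaults, "$")
    try:
        lesion = Lesion(mode=lz.get("mode", "none"), side=lz.get("side"))
    except (AttributeError, ValueError) as exc:
        raise RunConfigError(f"lesion: {exc}")

    pl = _get(data, "plant", {}, defaults, "$")
    try:
        plant = PlantParams(
            inertia=_get(pl, "inertia", 1.0, defaults, "plant"),
            damping=_get(pl, "damping", 2.0, defaults, "plant"),
            convergence=_get(pl, "convergence", 0.0, defaults, "plant"),
            process_precision=_get(pl, "process_precision", 1e4, defaults, "plant"),
            sensory_precision=_get(pl, "sensory_precision", 1e4, defaults, "plant"),
        )
    except (TypeError, ValueError) as exc:
        raise RunConfigError(f"plant: {exc}")
    phi = tuple(_get(pl, "phi", [0.3, 0.2], defaults, "plant"))
    dt = _get(pl, "dt", 1e-3, defaults, "plant")
    duration = _get(pl, "T", 2.0, defaults, "plant")

    pn = _get(data, "planner", {}, defaults, "$")
    policies = _parse_policies(_get(pn, "policies", [], defaults, "planner"),
                               place, defaults)
    belief_raw = _get(pn, "belief", None, defaults, "planner")
    belief = None if belief_raw is None else np.asarray(belief_raw, dtype=float)
    cluster_tol = _get(pn, "tol", 1e-6, defaults, "planner")

    room_label = data.get("room")
    if room_label is not None and room_label not in library.labels():
        raise RunConfigError(
            f"room {room_label!r} not in scene (have {library.labels()})"
        )

    seed = data.get("seed")
    if seed is not None:
        seed = int(seed)
    outdir = Path(_get(data, "outdir", "gazesim_out", defaults, "$"))
    if not outdir.is_absolute():
        outdir = base / outdir

    return RunConfig(
        library=library,
        scene_source=str(scene_source),
        room_label=room_label,
        pose=pose,
        eyes=eyes,
        baseline=float(baseline),
        light=light,
        array=array,
        sigma_freq=sigma_freq,
        resolution=int(resolution),
        lesion=lesion,
        plant=plant,
        phi=phi,
        dt=float(dt),
        duration=float(duration),
        policies=policies,
        belief=belief,
        cluster_tol=float(cluster_tol),
        seed=seed,
        outdir=outdir,
        digest=config_digest(raw),
        defaults_applied=defaults,
    )
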