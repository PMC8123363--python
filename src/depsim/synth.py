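"""Synthetic inputs: parameter fixtures, particle ensembles and noisy cell tracks.

Everything the experimental stages of the workflow would otherwise supply is
generated here:

* :func:`fixtures` loads the packaged parameter sets (media, beads, single-
  shell cell models, electrode geometry, release grids) as validated domain
  objects.
* :func:`generate_mixture` draws a bead mixture uniformly over the fluid
  region of the chamber, emulating a droplet of mixed 3.2 / 4.8 µm
  polystyrene suspension settling over the electrodes.
* :func:`generate_tracks` produces per-frame cell coordinates with a
  constant-velocity motion model plus isotropic Gaussian position noise,
  standing in for video-tracked cell trajectories.

All randomness flows from one explicit integer seed via
``numpy.random.default_rng``; the same seed reproduces the same output
bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dielectrics import DielectricMaterial, HomogeneousBead, ShelledCellModel
from .fields import ElectrodeGeometry, build_geometry
from .tracing import ReleaseGrid

__all__ = ["TrackModel", "fixtures", "generate_mixture", "generate_tracks"]


@dataclass(frozen=True)
class TrackModel:
    """Constant-velocity track generator with Gaussian position noise.

    ``velocity`` (µm/s) along ``direction``; frames at ``frame_interval``
    seconds (default video rate, 1/30 s); ``noise_sd`` µm isotropic noise.
    """

    velocity: float
    direction: tuple[float, float] = (1.0, 0.0)
    noise_sd: float = 0.5
    n_frames: int = 100
    frame_interval: float = 1.0 / 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_frames < 3:
            raise ValueError("n_frames must be >= 3")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        norm = float(np.hypot(*self.direction))
        if norm == 0:
            raise ValueError("direction must be a nonzero vector")
        object.__setattr__(
            self, "direction", (self.direction[0] / norm, self.direction[1] / norm)
        )


def _load_raw() -> dict:
    text = resources.files("depsim").joinpath("data/parameters.yaml").read_text()
    return yaml.safe_load(text)


def fixtures() -> dict:
    """Packaged parameter sets as validated domain objects.

    Keys: media ``di_water``, ``dmem_f12``, ``dmem``; beads ``ps_3p2um``,
    ``ps_4p8um`` (surface-conductance form) and ``ps_3p2um_printed``,
    ``ps_4p8um_printed`` (rounded tabulated conductivity as a bulk value);
    cells ``keratinocyte``, ``fibroblast``; plus ``geometry``, ``grid_1``,
    ``grid_2`` and the scalar blocks ``fluid``, ``densities``, ``drive``.
    """
    raw = _load_raw()
    out: dict = {}
    for name, m in raw["media"].items():
        out[name] = DielectricMaterial(
            conductivity=m["conductivity"],
            relative_permittivity=m["relative_permittivity"],
        )
    for name, b in raw["beads"].items():
        r = b["diameter_um"] / 2.0 * 1e-6
        out[name] = HomogeneousBead(
            radius=r,
            bulk_conductivity=b["bulk_conductivity"],
            surface_conductance=b["surface_conductance"],
            relative_permittivity=b["relative_permittivity"],
            label=name,
        )
        out[f"{name}_printed"] = HomogeneousBead(
            radius=r,
            bulk_conductivity=b["table_conductivity"],
            surface_conductance=0.0,
            relative_permittivity=b["relative_permittivity"],
            label=f"{name}_printed",
        )
    for name, c in raw["cells"].items():
        out[name] = ShelledCellModel(
            outer_dimensions=tuple(c["outer_dimensions_um"]),
            membrane=DielectricMaterial(**c["membrane"]),
            cytoplasm=DielectricMaterial(**c["cytoplasm"]),
            membrane_thickness=c["membrane_thickness_nm"] * 1e-9,
            label=name,
        )
    out["geometry"] = build_geometry(raw["geometry"])
    for name, g in raw["release_grids"].items():
        out[name] = ReleaseGrid(x_spec=tuple(g["x"]), y_spec=tuple(g["y"]))
    out["fluid"] = dict(raw["fluid"])
    out["densities"] = dict(raw["densities"])
    out["drive"] = dict(raw["drive"])
    return out


def generate_mixture(
    n_small: int,
    n_large: int,
    geometry: ElectrodeGeometry,
    seed: int,
) -> pd.DataFrame:
    """Uniformly place a bead mixture in the fluid region of the chamber.

    A 1:1 mixed suspension is emulated by independent uniform draws over the
    chamber rectangle, rejecting points that fall inside an electrode.
    Returns a DataFrame with columns ``label``, ``x_um``, ``y_um``.
    """
    if n_small < 0 or n_large < 0:
        raise ValueError("counts must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for label, count in (("ps_3p2um", n_small), ("ps_4p8um", n_large)):
        placed = 0
        while placed < count:
            m = count - placed
            x = rng.uniform(0.0, geometry.w4, m)
            y = rng.uniform(0.0, geometry.h3, m)
            ok = ~geometry.contains(x, y)
            for xi, yi in zip(x[ok], y[ok]):
                rows.append((label, float(xi), float(yi)))
            placed += int(ok.sum())
    return pd.DataFrame(rows, columns=["label", "x_um", "y_um"])


def generate_tracks(
    model: TrackModel,
    n_cells: int,
    path: str | Path | None = None,
    origin_spread: float = 100.0,
) -> pd.DataFrame:
    """Noisy constant-velocity tracks in the schema load_tracks expects.

    Each cell starts at a uniform random origin in
    [0, origin_spread]² µm and moves with the model's velocity along its
    direction; every frame position gets independent Gaussian noise of
    standard deviation ``noise_sd``.  If ``path`` is given the CSV is also
    written there.
    """
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    rng = np.random.default_rng(model.seed)
    t = np.arange(model.n_frames) * model.frame_interval
    d = np.asarray(model.direction)
    frames = []
    for k in range(n_cells):
        origin = rng.uniform(0.0, origin_spread, 2)
        clean = origin[None, :] + model.velocity * t[:, None] * d[None, :]
        noisy = clean + rng.normal(0.0, model.noise_sd, size=clean.shape)
        frames.append(
            pd.DataFrame(
                {
                    "cell": f"C{k + 1}",
                    "t_s": t,
                    "x_um": noisy[:, 0],
                    "y_um": noisy[:, 1],
                }
            )
        )
    df = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["cell", "t_s", "x_um", "y_um"])
    )
    if path is not None:
        df.to_csv(path, index=False)
    return df
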