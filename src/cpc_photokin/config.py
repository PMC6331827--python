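"""Run configuration: defaults, YAML round-trip and object builders.

A run configuration is a plain nested mapping (so it round-trips through
YAML without loss) with explicit units in the key names.  The shipped
defaults (``data/paper.yaml``, mirrored in :data:`DEFAULT_CONFIG`) describe
the pilot plant: Aeroxide P-25 optics, ten 1.2 m x 33 mm tubes, 30.2 L/min
recirculation from a 40 L system, 0.6 g/L slurry at 30 W/m^2.
"""

from __future__ import annotations

import copy
import hashlib
import json
import math
from importlib import resources

import yaml

from .hydrodynamics import FlowSpec
from .optics import OpticalProperties, SlurryState
from .radiation import CPCGeometry, build_polar_grid, lvrpa_field, vrpa_per_length
from .reactor import ReactorSpec

__all__ = [
    "DEFAULT_CONFIG",
    "load_config",
    "save_config",
    "merge_config",
    "config_hash",
    "build_optics",
    "build_geometry",
    "build_flow",
    "build_slurry",
    "build_reactor_spec",
    "build_field",
]

DEFAULT_CONFIG: dict = {
    "optics": {
        "kappa_m2kg": 174.7,
        "sigma_m2kg": 1295.8,
        "p_f": 0.110,
        "p_b": 0.710,
        "p_s": 0.045,
    },
    "geometry": {
        "tube_radius_mm": 16.5,
        "optical_path_mm": 33.0,
        "tube_length_m": 1.2,
        "n_tubes": 10,
        "acceptance_angle_deg": 90.0,
        "aperture_width_m": None,  # null -> ideal 2*pi*R
        "optical_efficiency": 1.0,
        "reflectivity": 0.85,
    },
    "flow": {
        "flow_L_min": 30.2,
        "diameter_mm": 33.0,
        "kinematic_viscosity_m2_s": 1.0e-6,
    },
    "operating": {
        "c_cat_g_L": 0.6,
        "i0_W_m2": 30.0,
        "v_t_L": 40.0,
    },
    "kinetics": {
        "fit_slope": 348947.0,
        "fit_intercept": 25773.0,
        "m_exp": 0.5,
        "calibrate_vrpa_W": 4.86,  # null -> use the uncalibrated model VRPA
    },
    "simulation": {
        "n_subreactors": 100,
        "n_r": 50,
        "n_theta": 72,
        "illumination_model": "direct-reflect",
        "toc0_ppm": 213.6,
        "t30w_min": 42.0,
    },
    "seed": 0,
}


def load_config(path=None) -> dict:
    """Load a YAML config; missing blocks/keys fall back to the defaults."""
    if path is None:
        with resources.files("cpc_photokin.data").joinpath("paper.yaml").open() as fh:
            user = yaml.safe_load(fh) or {}
    else:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
    return merge_config(user)


def merge_config(user: dict) -> dict:
    """Overlay a (possibly partial) user config on the defaults."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    for block, vals in (user or {}).items():
        if block not in cfg:
            raise ValueError(f"unknown config block {block!r}")
        if isinstance(cfg[block], dict):
            unknown = set(vals) - set(cfg[block])
            if unknown:
                raise ValueError(f"unknown keys in config block {block!r}: {sorted(unknown)}")
            cfg[block].update(vals)
        else:
            cfg[block] = vals
    return cfg


def save_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def config_hash(cfg: dict) -> str:
    """Stable short hash of a config (reproducibility logging)."""
    canon = json.dumps(cfg, sort_keys=True, default=float)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def build_optics(cfg: dict) -> OpticalProperties:
    o = cfg["optics"]
    return OpticalProperties(
        kappa=o["kappa_m2kg"], sigma=o["sigma_m2kg"],
        p_f=o["p_f"], p_b=o["p_b"], p_s=o["p_s"],
    )


def build_geometry(cfg: dict) -> CPCGeometry:
    g = cfg["geometry"]
    return CPCGeometry(
        tube_radius=g["tube_radius_mm"] / 1000.0,
        optical_path=g["optical_path_mm"] / 1000.0,
        tube_length=g["tube_length_m"],
        n_tubes=g["n_tubes"],
        acceptance_angle=math.radians(g["acceptance_angle_deg"]),
        aperture_width=g["aperture_width_m"],
        optical_efficiency=g["optical_efficiency"],
        reflectivity=g["reflectivity"],
    )


def build_flow(cfg: dict) -> FlowSpec:
    f = cfg["flow"]
    return FlowSpec.from_conditions(
        q=f["flow_L_min"] / 60.0e3,
        diameter=f["diameter_mm"] / 1000.0,
        kinematic_viscosity=f["kinematic_viscosity_m2_s"],
    )


def build_slurry(cfg: dict) -> SlurryState:
    return SlurryState(
        props=build_optics(cfg),
        c_cat=cfg["operating"]["c_cat_g_L"],
        delta=cfg["geometry"]["optical_path_mm"] / 1000.0,
    )


def build_reactor_spec(cfg: dict) -> ReactorSpec:
    return ReactorSpec(
        geometry=build_geometry(cfg),
        flow=build_flow(cfg),
        slurry=build_slurry(cfg),
        i0=cfg["operating"]["i0_W_m2"],
        v_t=cfg["operating"]["v_t_L"] / 1000.0,
        n_subreactors=cfg["simulation"]["n_subreactors"],
    )


def build_field(cfg: dict, geometry: CPCGeometry | None = None):
    """Build the LVRPA field, calibrating the optical efficiency if asked.

    If ``kinetics.calibrate_vrpa_W`` is set, the geometry's optical
    efficiency is rescaled so the whole-reactor VRPA matches that working
    point (the absolute illumination level depends on reflector details the
    model does not resolve; the calibration constant is explicit, not
    hidden).  Returns ``(field, geometry)``.
    """
    geometry = geometry or build_geometry(cfg)
    slurry = build_slurry(cfg)
    sim = cfg["simulation"]
    grid = build_polar_grid(geometry.tube_radius, sim["n_r"], sim["n_theta"])
    i0 = cfg["operating"]["i0_W_m2"]
    model = sim["illumination_model"]
    field = lvrpa_field(grid, slurry, i0, geometry, model=model)
    target = cfg["kinetics"].get("calibrate_vrpa_W")
    if target:
        vrpa = vrpa_per_length(field) * geometry.total_length
        eta = geometry.optical_efficiency * target / vrpa
        if not 0 < eta <= 1:
            raise ValueError(
                f"VRPA calibration requires optical efficiency {eta:.3g}, "
                "outside (0, 1]; adjust aperture/reflectivity instead"
            )
        geometry = CPCGeometry(
            tube_radius=geometry.tube_radius,
            optical_path=geometry.optical_path,
            tube_length=geometry.tube_length,
            n_tubes=geometry.n_tubes,
            acceptance_angle=geometry.acceptance_angle,
            aperture_width=geometry.aperture_width,
            optical_efficiency=eta,
            reflectivity=geometry.reflectivity,
        )
        field = lvrpa_field(grid, slurry, i0, geometry, model=model)
    return field, geometry
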