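"""Configuration schema, YAML fixtures and network construction.

Two fixture files ship with the package (``gravicor/data``):

* ``model.yaml`` — the woman-specific baseline: chamber elastance
  parameters, valve areas and rate coefficients, great-vessel compliances,
  blood properties, the myocardial-volume distribution and the pulmonary
  perfusion-pressure drop.  All values marked as assumptions in the file
  are free configuration, not hard-coded anywhere.
* ``stages.yaml`` — the five gestational stages: anthropometrics, heart
  rate, target cardiac output, perfusion pressure, per-organ flow
  fractions and valve-area scale factors.

The organ compartments are always derived at load time from the stage
targets (see :mod:`gravicor.parameterize`), so a network file never stores
redundant resistances.
"""

from __future__ import annotations

from importlib import resources

import yaml

from .errors import ConfigError
from .hemo import (
    CHAMBER_ORDER,
    VALVE_ORDER,
    BloodProperties,
    ChamberParams,
    GreatVesselParams,
    GreatVessels,
    NetworkConfig,
)
from .parameterize import (
    STAGES,
    StageConfig,
    build_stage_network,
    distribute_myocardium,
)

__all__ = [
    "load_base_config",
    "load_stages",
    "build_npc_network",
    "stage_network",
    "network_to_dict",
    "dump_network",
]


def _read_yaml(path_or_none, default_name):
    if path_or_none is None:
        ref = resources.files("gravicor.data") / default_name
        return yaml.safe_load(ref.read_text())
    with open(path_or_none) as fh:
        return yaml.safe_load(fh)


def load_base_config(path=None):
    cfg = _read_yaml(path, "model.yaml")
    for section in ("chambers", "valves", "vessels", "blood", "myocardium"):
        if section not in cfg:
            raise ConfigError(f"base config missing section {section!r}")
    return cfg


def load_stages(path=None):
    raw = _read_yaml(path, "stages.yaml")
    stages = {}
    for name in STAGES:
        if name not in raw:
            raise ConfigError(f"stage table missing stage {name!r}")
        d = raw[name]
        stages[name] = StageConfig(
            stage=name,
            weight_kg=d["weight_kg"],
            height_cm=d["height_cm"],
            hr_bpm=d["hr_bpm"],
            co_target_lmin=d["co_lmin"],
            perfusion_pressure_mmhg=d["perfusion_pressure_mmhg"],
            flow_fractions={k: v / 100.0 for k, v in d["flow_pct"].items()},
            valve_area_scale=d.get("valve_area_scale", {}),
            tau_sys=raw.get("tau_sys_s", 0.81),
            tau_pul=raw.get("tau_pul_s", 0.5),
        )
    return stages


def build_npc_network(base=None, stages=None) -> NetworkConfig:
    """Assemble the non-pregnant network from the fixture configs."""
    cfg = base if isinstance(base, dict) else load_base_config(base)
    stages = stages or load_stages()
    npc = stages["NPC"]

    chambers = {}
    for name in CHAMBER_ORDER:
        d = dict(cfg["chambers"][name])
        chambers[name] = ChamberParams(name=name, **d)
    myo = cfg["myocardium"]
    vwall = distribute_myocardium(
        myo["total_vmyo_ml"],
        [chambers[c] for c in CHAMBER_ORDER],
        mode=myo.get("distribution_mode", "Emax"),
        fractions=myo.get("fractions"),
    )
    for c, v in vwall.items():
        chambers[c].vwall = v

    from .hemo import ValveParams

    valves = {}
    rho = cfg["blood"].get("rho", 1.06)
    for name in VALVE_ORDER:
        d = dict(cfg["valves"][name])
        d.setdefault("blood_density", rho)
        valves[name] = ValveParams(name=name, **d)

    v = cfg["vessels"]
    vessels = GreatVessels(
        aorta=GreatVesselParams("aorta", **v["aorta"]),
        vena_cava=GreatVesselParams("vena_cava", **v["vena_cava"]),
        pulm_art=GreatVesselParams("pulm_art", **v["pulm_art"]),
        pulm_ven=GreatVesselParams("pulm_ven", **v["pulm_ven"]),
        R_pulm_bed=v.get("R_pulm_bed", 0.06),
    )

    proto = NetworkConfig(
        hr_bpm=npc.hr_bpm,
        chambers=chambers,
        valves=valves,
        organs={"placeholder": _placeholder_organ()},
        vessels=vessels,
        blood=BloodProperties(**cfg["blood"]),
        shape_coefficients=cfg.get("shape_coefficients", {}),
        meta={"pulm_perfusion_mmhg": cfg.get("pulmonary", {}).get(
            "perfusion_pressure_mmhg", 6.0)},
    )
    # derive organs + pulmonary parameters through the NPC stage targets
    return build_stage_network(npc, proto)


def _placeholder_organ():
    from .hemo import OrganParams

    return OrganParams("placeholder", 1, 1, 1, 1, 1)


def stage_network(name, base=None, stages=None) -> NetworkConfig:
    """Network of any stage, derived from the calibrated NPC layout."""
    stages = stages or load_stages()
    npc_net = build_npc_network(base, stages)
    if name == "NPC":
        return npc_net
    return build_stage_network(stages[name], npc_net)


def network_to_dict(net: NetworkConfig):
    """Serialisable full description of a network (round-trips by value)."""
    d = {
        "hr_bpm": net.hr_bpm,
        "blood": {"mu_poise": net.blood.mu_poise, "rho": net.blood.rho},
        "shape_coefficients": dict(net.shape_coefficients),
        "meta": dict(net.meta),
        "chambers": {},
        "valves": {},
        "organs": {},
        "vessels": {},
    }
    for c, ch in net.chambers.items():
        d["chambers"][c] = {
            k: getattr(ch, k)
            for k in ("Emax", "Emin", "tau1", "tau2", "m1", "m2", "t_onset",
                      "Vp0", "vwall", "shape")
        }
    for v, va in net.valves.items():
        d["valves"][v] = {
            k: getattr(va, k)
            for k in ("A_open", "A_closed", "K_open", "K_close",
                      "blood_density", "l_eff")
        }
    for o, og in net.organs.items():
        d["organs"][o] = {k: getattr(og, k) for k in ("Rart", "Rvb", "Rven", "Cart", "Cven")}
    for name, ves in zip(("aorta", "vena_cava", "pulm_art", "pulm_ven"),
                         net.vessels.as_tuple()):
        d["vessels"][name] = {"R": ves.R, "C": ves.C, "L": ves.L}
    d["vessels"]["R_pulm_bed"] = net.vessels.R_pulm_bed
    return d


def network_from_dict(d) -> NetworkConfig:
    from .hemo import OrganParams, ValveParams

    return NetworkConfig(
        hr_bpm=d["hr_bpm"],
        chambers={c: ChamberParams(name=c, **p) for c, p in d["chambers"].items()},
        valves={v: ValveParams(name=v, **p) for v, p in d["valves"].items()},
        organs={o: OrganParams(name=o, **p) for o, p in d["organs"].items()},
        vessels=GreatVessels(
            aorta=GreatVesselParams("aorta", **d["vessels"]["aorta"]),
            vena_cava=GreatVesselParams("vena_cava", **d["vessels"]["vena_cava"]),
            pulm_art=GreatVesselParams("pulm_art", **d["vessels"]["pulm_art"]),
            pulm_ven=GreatVesselParams("pulm_ven", **d["vessels"]["pulm_ven"]),
            R_pulm_bed=d["vessels"]["R_pulm_bed"],
        ),
        blood=BloodProperties(**d["blood"]),
        shape_coefficients=dict(d.get("shape_coefficients", {})),
        meta=dict(d.get("meta", {})),
    )


def dump_network(net: NetworkConfig, path):
    with open(path, "w") as fh:
        yaml.safe_dump(network_to_dict(net), fh, sort_keys=False)
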