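"""Configuration files, parameter tables, packaged fixtures and output writers.

Everything is plain delimited text: the site configuration is a flat YAML
document (see ``data/brasschaat.yaml`` for the documented schema), guild
parameters and the diet matrix are CSV tables, daily traces and MCMC chains
are CSV with headers.
"""

from __future__ import annotations

import warnings
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core_state import (
    GUILDS,
    POOLS,
    ConfigurationError,
    DietLink,
    ExternalInputs,
    GuildParams,
    LitterQuality,
    SiteConfig,
    SoilTexture,
)

__all__ = [
    "load_site_config",
    "read_guild_table",
    "read_diet_table",
    "brasschaat_config",
    "calibration_observations",
    "gmax_priors",
    "write_trace",
    "write_chain",
    "read_chain",
]

_KNOWN_SECTIONS = {
    "site": {"name", "latitude"},
    "soil": {"pct_sand", "pct_clay", "pct_som", "bulk_density", "ph", "layer_thickness"},
    "structure": {
        "f_pv", "pv_bmax", "ve_ratio", "burrow_lifespan_days", "k_ag", "c_ag", "pv_ag_cap",
    },
    "pools": set(POOLS),
    "quality": {
        "cn_litter", "rec_litter", "cn_som", "rec_som",
        "cn_litterfall", "rec_litterfall", "cn_rootlitter", "rec_rootlitter",
    },
    "inputs": {
        "litter_fall_annual", "root_litter_annual", "myc_allocation_annual",
        "exudation_daily", "root_biomass",
    },
    "hydrology": {
        "i_max_mat", "i_max_mat_subsoil", "fc_includes_meso", "initial_water", "pv_text",
    },
    "leaching": {"f_dom", "dom_return_rate", "a_kd", "b_kd", "c_kd"},
    "bioturbation": {"litter_rate", "som_rate"},
}


def _data_path(name: str) -> Path:
    return Path(resources.files("soilweb").joinpath("data", name))


def read_guild_table(path) -> dict:
    """Read the guild parameter CSV (one row per guild) into GuildParams."""
    df = pd.read_csv(path)
    out = {}
    for _, row in df.iterrows():
        out[row["guild"]] = GuildParams(
            name=row["guild"],
            g_max=float(row["g_max"]),
            r=float(row["r"]),
            d=float(row["d"]),
            f_faec=float(row["f_faec"]),
            m_faec=float(row["m_faec"]),
            cn=float(row["cn"]),
            p_m_cn=float(row["p_m_cn"]),
            p_m_rec=float(row["p_m_rec"]),
            t_min=float(row["t_min"]),
            t_opt=float(row["t_opt"]),
            t_max=float(row["t_max"]),
            q10=float(row["q10"]),
            size_class=str(row["size_class"]),
        )
    missing = [g for g in GUILDS if g not in out]
    if missing:
        raise ConfigurationError(f"guild table lacks rows for: {', '.join(missing)}")
    return out


def read_diet_table(path) -> list:
    """Read the diet edge-list CSV (consumer, substrate, k_s[, pore_classes])."""
    df = pd.read_csv(path)
    links = []
    for _, row in df.iterrows():
        classes = ()
        if "pore_classes" in df.columns and not pd.isna(row.get("pore_classes")):
            classes = tuple(int(c) for c in str(row["pore_classes"]).split(";"))
        links.append(
            DietLink(
                consumer=str(row["consumer"]),
                substrate=str(row["substrate"]),
                k_s=float(row["k_s"]),
                pore_classes=classes,
            )
        )
    return links


def _check_keys(raw: dict, strict: bool) -> None:
    for section, keys in raw.items():
        if section not in _KNOWN_SECTIONS:
            msg = f"unknown configuration section {section!r}"
            if strict:
                raise ConfigurationError(msg)
            warnings.warn(msg, stacklevel=3)
            continue
        if not isinstance(keys, dict):
            raise ConfigurationError(f"section {section!r} must be a mapping")
        unknown = set(keys) - _KNOWN_SECTIONS[section]
        if unknown:
            msg = f"unknown keys in section {section!r}: {', '.join(sorted(unknown))}"
            if strict:
                raise ConfigurationError(msg)
            warnings.warn(msg, stacklevel=3)


def _require(section: dict, name: str, key: str):
    if key not in section:
        raise ConfigurationError(f"missing required field {name}.{key}")
    return section[key]


def load_site_config(
    source, guilds=None, diet=None, strict: bool = True
) -> SiteConfig:
    """Build a :class:`SiteConfig` from a YAML file (or a parsed dict).

    ``guilds``/``diet`` may be paths to CSV tables or already-built objects;
    the packaged defaults are used when omitted.  Unknown keys raise in
    strict mode and warn otherwise.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            raw = yaml.safe_load(fh)
    else:
        raw = dict(source)
    if not isinstance(raw, dict):
        raise ConfigurationError("site configuration must be a mapping")
    _check_keys(raw, strict)

    soil = raw.get("soil", {})
    texture = SoilTexture(
        pct_sand=float(_require(soil, "soil", "pct_sand")),
        pct_clay=float(_require(soil, "soil", "pct_clay")),
        pct_som=float(_require(soil, "soil", "pct_som")),
        bulk_density=float(_require(soil, "soil", "bulk_density")),
        ph=float(_require(soil, "soil", "ph")),
        layer_thickness=float(soil.get("layer_thickness", 0.9)),
    )
    pools = {p: float(v) for p, v in raw.get("pools", {}).items()}
    q = raw.get("quality", {})
    inp = raw.get("inputs", {})
    inputs = ExternalInputs(
        litter_fall=float(inp.get("litter_fall_annual", 0.0)) / 365.0,
        root_litter=float(inp.get("root_litter_annual", 0.0)) / 365.0,
        myc_allocation=float(inp.get("myc_allocation_annual", 0.0)) / 365.0,
        exudation=float(inp.get("exudation_daily", 0.0)),
        root_biomass=float(inp.get("root_biomass", 0.0)),
    )
    if guilds is None:
        guilds = read_guild_table(_data_path("guilds.csv"))
    elif isinstance(guilds, (str, Path)):
        guilds = read_guild_table(guilds)
    if diet is None:
        diet = read_diet_table(_data_path("diet.csv"))
    elif isinstance(diet, (str, Path)):
        diet = read_diet_table(diet)

    st = raw.get("structure", {})
    hyd = raw.get("hydrology", {})
    le = raw.get("leaching", {})
    bt = raw.get("bioturbation", {})
    i_max_mat = hyd.get("i_max_mat", None)
    return SiteConfig(
        texture=texture,
        initial_pools=pools,
        litter_quality=LitterQuality(
            float(_require(q, "quality", "cn_litter")),
            float(_require(q, "quality", "rec_litter")),
        ),
        som_quality=LitterQuality(
            float(_require(q, "quality", "cn_som")),
            float(_require(q, "quality", "rec_som")),
        ),
        litterfall_quality=LitterQuality(
            float(q.get("cn_litterfall", q["cn_litter"])),
            float(q.get("rec_litterfall", q["rec_litter"])),
        ),
        rootlitter_quality=LitterQuality(
            float(q.get("cn_rootlitter", q["cn_som"])),
            float(q.get("rec_rootlitter", q["rec_som"])),
        ),
        inputs=inputs,
        guilds=guilds,
        diet=diet,
        f_pv=float(st.get("f_pv", 0.5)),
        pv_bmax=float(st.get("pv_bmax", 50.0)),
        ve_ratio=float(st.get("ve_ratio", 0.05)),
        burrow_lifespan_days=float(st.get("burrow_lifespan_days", 3650.0)),
        k_ag=float(st.get("k_ag", 2.0)),
        c_ag=float(st.get("c_ag", 10.0)),
        pv_ag_cap=float(st.get("pv_ag_cap", 20.0)),
        i_max_mat=None if i_max_mat is None else float(i_max_mat),
        i_max_mat_subsoil=float(hyd.get("i_max_mat_subsoil", 50.0)),
        fc_includes_meso=bool(hyd.get("fc_includes_meso", False)),
        initial_water=hyd.get("initial_water", "field_capacity"),
        pv_text=hyd.get("pv_text", None),
        f_dom=float(le.get("f_dom", 0.02)),
        dom_return_rate=float(le.get("dom_return_rate", 0.05)),
        a_kd=float(le.get("a_kd", 0.001226)),
        b_kd=float(le.get("b_kd", 0.000212)),
        c_kd=float(le.get("c_kd", 0.00374)),
        bioturb_litter_rate=float(bt.get("litter_rate", 0.01)),
        bioturb_som_rate=float(bt.get("som_rate", 0.05)),
        name=str(raw.get("site", {}).get("name", "site")),
        latitude=float(raw.get("site", {}).get("latitude", 51.3)),
    )


def brasschaat_config() -> SiteConfig:
    """The packaged sandy pine-forest site fixture."""
    return load_site_config(_data_path("brasschaat.yaml"))


def calibration_observations() -> pd.DataFrame:
    """Packaged pool-stability observations (pool, value, sd in g C m^-3)."""
    return pd.read_csv(_data_path("calibration_obs.csv"))


def gmax_priors() -> dict:
    """Packaged uniform prior bounds on g_max per guild: {name: (lo, hi)}."""
    df = pd.read_csv(_data_path("gmax_priors.csv"))
    return {row["guild"]: (float(row["lower"]), float(row["upper"])) for _, row in df.iterrows()}


def write_trace(result, path) -> None:
    """Write a daily trace as CSV (one row per day, documented header)."""
    result.to_dataframe().to_csv(path, index=False)


def write_chain(chain, path) -> None:
    """Write an MCMC chain as CSV: one row per iteration, parameters +
    log-likelihood + accepted flag."""
    df = pd.DataFrame(chain.params, columns=list(chain.names))
    df["log_likelihood"] = chain.loglik
    df["accepted"] = chain.accepted.astype(int)
    df.to_csv(path, index=False)


def read_chain(path):
    from .calibration import Chain

    df = pd.read_csv(path)
    names = [c for c in df.columns if c not in ("log_likelihood", "accepted")]
    return Chain(
        params=df[names].to_numpy(dtype=float),
        loglik=df["log_likelihood"].to_numpy(dtype=float),
        accepted=df["accepted"].to_numpy(dtype=bool),
        names=tuple(names),
    )
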