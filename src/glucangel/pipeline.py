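"""Config-driven end-to-end runs.

A run config (YAML) names a seed, an output directory and a list of stages
with per-stage parameters; unknown keys are rejected before any
computation.  Each stage writes TSV/JSON tables into the output directory,
prefixed with provenance headers (package version, seed, config hash).
Numeric tables are deterministic for a fixed seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import builder, conformation, interactions, sfactor, synthetic
from . import __version__
from .elasticity import bulk_modulus, elastic_constants, pade_young

logger = logging.getLogger("glucangel")

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]

_KNOWN_TOP_KEYS = {"seed", "outdir", "stages"}
_KNOWN_STAGES = {
    "build",
    "hbonds",
    "links",
    "end_to_end",
    "structure_factor",
    "elastic_volume",
    "elastic_strain",
    "pade",
    "xrd",
    "report",
}


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    seed: int
    outdir: Path
    stages: list[dict] = field(default_factory=list)
    config_hash: str = ""

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
        unknown = set(raw) - _KNOWN_TOP_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "outdir" not in raw:
            raise ValueError("config must set 'outdir'")
        stages = raw.get("stages", [])
        for st in stages:
            if "name" not in st:
                raise ValueError("every stage needs a 'name'")
            if st["name"] not in _KNOWN_STAGES:
                raise ValueError(f"unknown stage {st['name']!r}")
            extra = set(st) - {"name", "params"}
            if extra:
                raise ValueError(
                    f"unknown keys in stage {st['name']!r}: {sorted(extra)}"
                )
        # provenance hash covers the scientific configuration, not the
        # output location
        hashed = {k: v for k, v in raw.items() if k != "outdir"}
        digest = hashlib.sha256(
            yaml.safe_dump(hashed, sort_keys=True).encode()
        ).hexdigest()[:12]
        return cls(
            seed=int(raw.get("seed", 0)),
            outdir=Path(raw["outdir"]),
            stages=stages,
            config_hash=digest,
        )


def _provenance(cfg: RunConfig) -> str:
    return (
        f"# glucangel {__version__}\n"
        f"# seed {cfg.seed}\n"
        f"# config {cfg.config_hash}\n"
    )


def _write_table(cfg: RunConfig, name: str, df: pd.DataFrame) -> Path:
    path = cfg.outdir / name
    with open(path, "w") as fh:
        fh.write(_provenance(cfg))
        df.to_csv(fh, sep="\t", index=False, float_format="%.8g")
    return path


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in order; returns the report bundle.

    Stage outputs land in ``config.outdir``.  A stage failure aborts the
    run with the failing stage named; tables already written are retained.
    """
    cfg = config
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    ctx: dict = {"seed": cfg.seed}
    bundle: dict = {"seed": cfg.seed, "config": cfg.config_hash, "outputs": {}}
    for st in cfg.stages:
        name = st["name"]
        params = dict(st.get("params") or {})
        t0 = _time.perf_counter()
        try:
            outputs = _STAGE_FNS[name](cfg, ctx, params)
        except Exception as exc:
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        dt = _time.perf_counter() - t0
        logger.info("stage %s finished in %.2f s", name, dt)
        bundle["outputs"][name] = outputs
    (cfg.outdir / "report.json").write_text(json.dumps(bundle, indent=2, default=str))
    return bundle


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_build(cfg: RunConfig, ctx: dict, p: dict) -> dict:
    scale = p.pop("scale", 0.25)
    composition = p.pop("composition", "100:0")
    n_frames = p.pop("n_frames", 3)
    _reject_extra("build", p)
    built, frames, rep = synthetic.gen_toy_hydrogel(
        scale=scale, seed=cfg.seed, composition=composition, n_frames=n_frames
    )
    ctx.update(built=built, frames=frames)
    comp = pd.DataFrame([built.report])
    _write_table(cfg, "composition.tsv", comp)
    return {
        "composition": built.report,
        "crystallinity_pct": builder.crystallinity_degree(built, ndigits=1),
    }


def _stage_hbonds(cfg: RunConfig, ctx: dict, p: dict) -> dict:
    _require(ctx, "frames", "hbonds")
    d_max = p.pop("d_max", 3.2)
    ang_max = p.pop("ang_max", 40.0)
    _reject_extra("hbonds", p)
    built = ctx["built"]
    tallies = []
    for fr in ctx["frames"]:
        hbs = interactions.detect_hbonds(fr, built.topology, d_max, ang_max)
        tallies.append(interactions.tally_hbonds(hbs))
    df = pd.DataFrame(tallies)
    mean = df.mean()
    se = df.std(ddof=1) / np.sqrt(len(df)) if len(df) > 1 else df.iloc[0] * 0
    out = pd.DataFrame({"class": mean.index, "mean": mean.values, "se": se.values})
    _write_table(cfg, "hbonds.tsv", out)
    return {"total_mean": float(df.sum(axis=1).mean())}


def _stage_links(cfg: RunConfig, ctx: dict, p: dict) -> dict:
    _require(ctx, "frames", "links")
    cutoff = p.pop("cutoff", 3.6)
    ring_window = p.pop("ring_window", 2)
    _reject_extra("links", p)
    built = ctx["built"]
    fr = ctx["frames"][-1]
    contacts = interactions.short_contacts(fr, built.topology, cutoff)
    links = interactions.cluster_links(contacts, built.topology, ring_window)
    stats = interactions.network_stats(links, built.topology)
    rows = [
        {
            "unit_a": lk.unit_a, "unit_b": lk.unit_b,
            "kind_a": lk.kind_a, "kind_b": lk.kind_b, "nc": lk.nc,
        }
        for lk in links
    ]
    _write_table(cfg, "links.tsv", pd.DataFrame(
        rows, columns=["unit_a", "unit_b", "kind_a", "kind_b", "nc"]))
    ctx["links_stats"] = stats
    return {k: v for k, v in stats.items() if k != "links_per_unit"}


def _stage_end_to_end(cfg: RunConfig, ctx: dict, p: dict) -> dict:
    _require(ctx, "frames", "end_to_end")
    species = p.pop("species", "cellulose")
    exclude = p.pop("exclude_fibers", True)
    bin_width = p.pop("bin_width", 5.0)
    _reject_extra("end_to_end", p)
    built = ctx["built"]
    values = conformation.end_to_end(
        ctx["frames"][-1], built.topology, species, exclude_fiber_chains=exclude
    )
    dist = conformation.radial_distribution(values, bin_width, species=species)
    _write_table(cfg, f"p_l_{species}.tsv", pd.DataFrame(
        {"l_A": dist.bin_centers, "P_l": dist.density}))
    return {"mean_l_A": dist.mean, "se": dist.se, "n_chains": dist.n_chains}


def _stage_structure_factor(cfg: RunConfig, ctx: dict, p: dict) -> dict:
    _require(ctx, "frames", "structure_factor")
    k_max = p.pop("k_max", 0.8)
    _reject_extra("structure_factor", p)
    built = ctx["built"]
    coords = [
        sfactor.ring_centroids(fr, built.topology) for fr in ctx["frames"]
    ]
    spec = sfactor.structure_factor(
        coords, built.frame.box, k_max,
        rng=np.random.default_rng(cfg.seed), selection="rings",
    )
    _write_table(cfg, "sq_rings.tsv", pd.DataFrame(
        {"k": spec.bin_centers, "S": spec.s_of_k, "n_vectors": spec.n_vectors}))
    return {"n_bins": int(len(spec.bin_centers))}


def _stage_elastic_volume(cfg: RunConfig, ctx: dict, p: dict) -> dict:
    B = p.pop("B_GPa", 1.96)
    n = p.pop("n", 100_000)
    _reject_extra("elastic_volume", p)
    series, rep = synthetic.gen_fluctuations("volume", B=B, n=n, seed=cfg.seed)
    est = bulk_modulus(series)
    _write_table(cfg, "bulk_modulus.tsv", pd.DataFrame(
        [{"B_GPa": est.B, "se_GPa": est.se, "planted_GPa": B}]))
    return {"B_GPa": est.B, "se_GPa": est.se}


def _stage_elastic_strain(cfg: RunConfig, ctx: dict, p: dict) -> dict:
    c11 = p.pop("C11_GPa", 1.9966)
    c12 = p.pop("C12_GPa", 1.9417)
    n = p.pop("n", 100_000)
    _reject_extra("elastic_strain", p)
    series, rep = synthetic.gen_fluctuations(
        "strain", C11=c11, C12=c12, n=n, seed=cfg.seed
    )
    est = elastic_constants(series)
    _write_table(cfg, "elastic_constants.tsv", pd.DataFrame([{
        "C11_GPa": est.C11, "C12_GPa": est.C12, "B_GPa": est.B,
        "Y_MPa": est.Y, "se_Y_MPa": est.se_Y,
    }]))
    return {"Y_MPa": est.Y, "B_GPa": est.B}


def _stage_pade(cfg: RunConfig, ctx: dict, p: dict) -> dict:
    eval_at = tuple(p.pop("eval_at", (0.3, 1.5)))
    noise = p.pop("noise", 0.02)
    _reject_extra("pade", p)
    df, rep = synthetic.gen_stress_strain(noise=noise, seed=cfg.seed)
    curve = pade_young(
        df["stress_MPa"].to_numpy(), df["strain"].to_numpy(),
        strain_se=df["strain_se"].to_numpy() if noise > 0 else None,
        eval_at=eval_at,
    )
    _write_table(cfg, "young_vs_stress.tsv", pd.DataFrame(
        {"stress_MPa": list(curve.young), "Y_MPa": list(curve.young.values())}))
    return {"Y_MPa": {str(k): v for k, v in curve.young.items()}}


def _stage_xrd(cfg: RunConfig, ctx: dict, p: dict) -> dict:
    from .xrd import deconvolve

    cri = p.pop("CrI_pct", 57.0)
    noise = p.pop("noise", 0.01)
    _reject_extra("xrd", p)
    diff, rep = synthetic.gen_diffractogram(cri, noise=noise, seed=cfg.seed)
    fit = deconvolve(diff)
    _write_table(cfg, "xrd_fit.tsv", pd.DataFrame([
        {"label": pk.label, "center": pk.center, "fwhm": pk.fwhm,
         "area": pk.area, "crystalline": pk.crystalline}
        for pk in fit.peaks
    ]))
    return {"CrI_pct": fit.crystallinity, "planted_pct": cri}


def _stage_report(cfg: RunConfig, ctx: dict, p: dict) -> dict:
    _reject_extra("report", p)
    return {"stages_run": [k for k in ctx if k not in ("seed",)]}


def _require(ctx: dict, key: str, stage: str) -> None:
    if key not in ctx:
        raise ValueError(f"stage {stage!r} needs a prior 'build' stage")


def _reject_extra(stage: str, params: dict) -> None:
    if params:
        raise ValueError(f"unknown parameters for stage {stage!r}: {sorted(params)}")


_STAGE_FNS = {
    "build": _stage_build,
    "hbonds": _stage_hbonds,
    "links": _stage_links,
    "end_to_end": _stage_end_to_end,
    "structure_factor": _stage_structure_factor,
    "elastic_volume": _stage_elastic_volume,
    "elastic_strain": _stage_elastic_strain,
    "pade": _stage_pade,
    "xrd": _stage_xrd,
    "report": _stage_report,
}
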