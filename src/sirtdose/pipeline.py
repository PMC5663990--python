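"""End-to-end orchestration: phantom -> territories -> uptake -> dose -> plan.

Given a :class:`RunConfig`, :func:`run_pipeline` generates (or loads) the
input volumes, computes arterial territories from the vessel mask, builds the
classical (0-mm margin) and territorial (11-mm margin) partition tables,
plans activities under the chosen thresholds, renders dose maps, and writes
everything to the output directory.  Runs are deterministic under a fixed
seed, and every JSON artifact carries the config hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .dosimetry import render_dose_map, tm_doses
from .errors import InvalidInputError
from .image import VolumeImage, ensure_same_grid, read_volume, write_volume
from .phantom import PhantomSpec, generate
from .planning import PatientBody, Thresholds, bsa_activity, compare_models, plan_activity
from .territories import assign_territories, build_graph, group_branches
from .uptake import MarginPolicy, lung_shunt_fraction, partition_counts, tn_ratio

log = logging.getLogger("sirtdose")


@dataclass
class RunConfig:
    """Configuration for one pipeline run.

    Either ``phantom`` is set (synthetic run) or the volume paths are given.
    """

    out_dir: str = "sirtdose_out"
    seed: int = 0
    phantom: PhantomSpec | None = None
    counts_path: str | None = None
    liver_path: str | None = None
    lung_path: str | None = None
    tumor_paths: list[str] = field(default_factory=list)
    vessel_path: str | None = None
    models: tuple[str, ...] = ("PM", "TM", "BSA")
    margin_mm: float = 11.0
    margin_disposition: str = "excluded_partition"
    density_kg_per_L: float = 1.05
    lung_density_kg_per_L: float = 0.30
    grouping_generation: int = 2
    thresholds: str = "t1"
    body_height_m: float = 1.70
    body_weight_kg: float = 70.0
    write_png: bool = False

    def config_hash(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            raise TypeError(type(o))

        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=enc)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _load_inputs(config: RunConfig):
    if config.phantom is not None:
        spec = dataclasses.replace(config.phantom, rng_seed=config.seed)
        bundle = generate(spec)
        return bundle
    if tuple(m.upper() for m in config.models) == ("BSA",):
        needed = {"liver": config.liver_path}
    else:
        needed = {
            "counts": config.counts_path,
            "liver": config.liver_path,
            "vessels": config.vessel_path,
        }
    missing = [k for k, v in needed.items() if v is None]
    if missing:
        raise InvalidInputError(f"missing inputs for a non-phantom run: {missing}")
    return None


def run_pipeline(config: RunConfig) -> dict:
    """Run the full chain and write artifacts; returns a summary dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()

    fh = logging.FileHandler(out / "run.log", mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)
    log.setLevel(logging.INFO)
    log.info("sirtdose %s, config hash %s, seed %d", __version__, chash, config.seed)

    try:
        models = tuple(m.upper() for m in config.models)
        if models == ("BSA",):
            # BSA needs no counts, no lung mask, no vessels: volumes + body only
            if config.phantom is not None:
                bundle = generate(
                    dataclasses.replace(config.phantom, rng_seed=config.seed)
                )
                liver = bundle.liver_mask
                tumor_union = bundle.tumor_union()
                spacing = bundle.spacing
            else:
                liver = read_volume(config.liver_path)
                spacing = liver.spacing
                tumor_union = np.zeros(liver.shape, dtype=bool)
                for p in config.tumor_paths:
                    t = read_volume(p)
                    ensure_same_grid(liver, t, what="liver/tumor masks")
                    tumor_union |= t.data.astype(bool)
            voxel_mL = float(np.prod(spacing)) / 1000.0
            v_t = float(tumor_union.sum()) * voxel_mL
            v_total = float(liver.data.astype(bool).sum()) * voxel_mL
            body = PatientBody(
                config.body_height_m, config.body_weight_kg, v_t, max(v_total, v_t)
            )
            summary = {
                "config_hash": chash,
                "bsa_A0_GBq": bsa_activity(body),
                "tumor_volume_mL": v_t,
                "total_volume_mL": max(v_total, v_t),
            }
            (out / "plan_bsa.json").write_text(json.dumps(summary, indent=2))
            (out / "summary.json").write_text(json.dumps(summary, indent=2))
            log.info("BSA-only run complete: %s", out)
            return summary

        bundle = _load_inputs(config)
        if bundle is not None:
            spacing = bundle.spacing
            counts = bundle.count_image
            liver = bundle.liver_mask
            lung = bundle.lung_mask
            tumors = bundle.tumor_masks
            vessels = bundle.vessel_mask
            root_hint = bundle.spec.vessel_root_mm
            for name, vol in [
                ("counts", counts),
                ("liver_mask", liver),
                ("lung_mask", lung),
                ("vessel_mask", vessels),
            ]:
                write_volume(vol, out / f"{name}.nii.gz")
            for i, t in enumerate(tumors, 1):
                write_volume(t, out / f"tumor_{i:02d}_mask.nii.gz")
            write_volume(
                VolumeImage(bundle.territory_truth.labels, spacing),
                out / "territory_truth.nii.gz",
            )
            (out / "phantom_truth.json").write_text(
                json.dumps(
                    {
                        "config_hash": chash,
                        "true_TN": bundle.spec.true_TN,
                        "true_lung_shunt": bundle.spec.true_lung_shunt,
                        "n_branches_truth": len(bundle.centerline_truth.branches),
                    },
                    indent=2,
                )
            )
        else:
            counts = read_volume(config.counts_path)
            liver = read_volume(config.liver_path)
            vessels = read_volume(config.vessel_path)
            lung = read_volume(config.lung_path) if config.lung_path else None
            tumors = [read_volume(p) for p in config.tumor_paths]
            vols = [v for v in [counts, liver, vessels, lung, *tumors] if v is not None]
            ensure_same_grid(*vols, what="pipeline inputs")
            spacing = counts.spacing
            root_hint = None

        # territories from the vessel mask
        from .territories import skeletonize_vessels

        skel = skeletonize_vessels(vessels.data)
        prune = 2.0 * float(np.linalg.norm(spacing))
        graph = build_graph(skel, spacing, root_hint_mm=root_hint, prune_spurs_mm=prune)
        b2t, names = group_branches(graph, generation=config.grouping_generation)
        tumor_union = np.zeros(liver.shape, dtype=bool)
        for t in tumors:
            tumor_union |= t.data.astype(bool)
        labelmap = assign_territories(
            liver.data.astype(bool) & ~tumor_union,
            graph,
            spacing,
            branch_to_territory=b2t,
            territory_names=names,
        )
        write_volume(VolumeImage(labelmap.labels, spacing), out / "territories.nii.gz")
        (out / "territories.json").write_text(
            json.dumps(
                {
                    "config_hash": chash,
                    "branch_to_territory": {str(k): v for k, v in b2t.items()},
                    "territory_names": {str(k): v for k, v in names.items()},
                },
                indent=2,
            )
        )
        (out / "centerline_graph.json").write_text(graph.to_json())

        # partition tables: PM classical (0-mm margin), TM with margin
        common = dict(
            count_image=counts.data,
            territory_labels=labelmap.labels,
            tumor_masks=[t.data for t in tumors],
            lung_mask=lung.data if lung is not None else None,
            spacing=spacing,
            liver_mask=liver.data,
            density_kg_per_L=config.density_kg_per_L,
            lung_density_kg_per_L=config.lung_density_kg_per_L,
            territory_names=names,
        )
        pm_table = partition_counts(margin_policy=MarginPolicy(0.0), **common)
        tm_table = partition_counts(
            margin_policy=MarginPolicy(config.margin_mm, config.margin_disposition),
            **common,
        )
        pm_table.to_csv(out / "partitions_pm.csv")
        tm_table.to_csv(out / "partitions_tm.csv")

        thresholds = Thresholds.from_tag(config.thresholds)
        pm_plan = plan_activity("PM", pm_table, thresholds)
        tm_plan = plan_activity("TM", tm_table, thresholds)
        voxel_mL = float(np.prod(spacing)) / 1000.0
        v_t = float(tumor_union.sum()) * voxel_mL
        v_total = float(liver.data.astype(bool).sum()) * voxel_mL
        body = PatientBody(
            config.body_height_m, config.body_weight_kg, v_t, max(v_total, v_t)
        )
        report = compare_models(pm_table, tm_table, thresholds, body)
        report.to_csv(out / "report.csv")
        for plan in (pm_plan, tm_plan):
            d = plan.to_dict()
            d["config_hash"] = chash
            (out / f"plan_{plan.model.lower()}.json").write_text(json.dumps(d, indent=2))
        (out / "plan_bsa.json").write_text(
            json.dumps(
                {"model": "BSA", "A0_GBq": bsa_activity(body), "config_hash": chash},
                indent=2,
            )
        )

        # dose maps at the planned activities
        L = lung_shunt_fraction(tm_table)
        tm_dosed = tm_doses(tm_plan.a0_GBq, L, tm_table)
        dose_map = render_dose_map(tm_dosed)
        write_volume(
            VolumeImage(dose_map.astype(np.float32), spacing), out / "dose_map_tm.nii.gz"
        )
        L_pm = lung_shunt_fraction(pm_table)
        pm_dosed = tm_doses(pm_plan.a0_GBq, L_pm, pm_table)
        write_volume(
            VolumeImage(render_dose_map(pm_dosed).astype(np.float32), spacing),
            out / "dose_map_pm.nii.gz",
        )
        if config.write_png:
            from .viz import save_dose_montage

            save_dose_montage(dose_map, spacing, out / "dose_map_tm.png")

        summary = {
            "config_hash": chash,
            "lung_shunt": L,
            "tn_ratio_pm": tn_ratio(pm_table),
            "pm": pm_plan.to_dict(),
            "tm": tm_plan.to_dict(),
            "bsa_A0_GBq": bsa_activity(body),
            "n_territories": len(set(b2t.values())),
            "n_branches": len(graph.branches),
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=2))
        log.info("pipeline complete: %s", out)
        return summary
    except Exception:
        log.exception("pipeline failed")
        raise
    finally:
        log.removeHandler(fh)
        fh.close()
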