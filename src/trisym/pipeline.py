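"""End-to-end orchestration: complete → dock → classify → bridge → holo.

The pipeline reproduces the full modeling workflow for a trimeric
single-pass receptor: complete the lone protomer from a homolog template,
enumerate and rank C3-symmetric ectodomain trimers, classify their termini,
compute transmembrane-bundle ring statistics from an ensemble, test whether
the unresolved juxtamembrane linker can bridge ectodomain and
transmembrane rings, and finally place the protomer on a ligand-bound
template and ask how far a hinge rotation can relieve the resulting strain.

Everything is driven by a validated configuration mapping (YAML on disk);
all randomness is seeded, so a rerun with the same configuration reproduces
the JSON summary byte for byte.  Inputs are either generated fixtures
(fully offline) or structure files; accession fetching is an explicit
opt-in on the CLI.
"""

from __future__ import annotations

import copy
import json
import logging
import os

import numpy as np
from scipy.spatial.transform import Rotation

from . import __version__
from .assembly import PoseGrid, enumerate_c3_poses
from .completion import complete_gaps
from .fixtures import (
    make_c3_bundle,
    make_gapped_pair,
    make_noisy_ensemble,
)
from .geometry import (
    MembraneSlab,
    classify_termini,
    ensemble_ring_stats,
    interface_residues,
    linker_bridge_feasible,
    ring_compatibility,
    ring_distance,
    tilt_angle,
)
from .holo import HingeSearch, hinge_rotate, place_on_template
from .structure_io import (
    Conformer,
    Ensemble,
    NumberingMap,
    RegionSpan,
    detect_gaps,
    parse_span,
    read_structure,
    write_structure,
)
from .superpose import core_align

logger = logging.getLogger(__name__)

SUMMARY_SCHEMA_VERSION = 1


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


DEFAULT_CONFIG: dict = {
    "seed": 0,
    "numbering": {"signal_peptide_length": 16, "file_to_precursor_offset": 0},
    "inputs": {
        # fixtures: generate everything; files: read the given paths
        "kind": "fixtures",
        "target": None,
        "template": None,
        "tm_ensemble": None,
        "holo_template": None,
        "holo_receptor_chains": None,
    },
    "fixtures": {
        "protein_length": 60,
        "deleted_span": [28, 39],
        "fold": "rod",
        "bundle": {"n_residues": 24, "ring_radius": 6.0, "tilt": 0.0,
                   "phase": 0.0, "helix_radius": 1.0, "start_number": 101},
        "ensemble": {"n_conformers": 15, "sigma_core": 0.2, "sigma_end": 2.0},
        "holo_splay_tilt": 35.0,
        "holo_ring_radius": 16.0,
    },
    "align": {"seed_mapping": "sequence", "trim_cutoff": 3.5, "max_iter": 10},
    "complete": {"anchor_k": 4},
    "dock": {
        "top_k": 4,
        "pre_orient": True,
        "contact_shell": 8.0,
        "clash_cutoff": 4.0,
        "w_clash": 10.0,
        "grid": {
            "alpha_range": [0.0, 360.0],
            "beta_range": [0.0, 180.0],
            "gamma_range": [0.0, 0.0],
            "angular_step": 15.0,
            "radial_range": [4.0, 10.0],
            "radial_step": 2.0,
            "axial_range": [0.0, 0.0],
            "axial_step": 2.0,
        },
    },
    "classify": {"nt_residue": None, "ct_residue": None, "threshold": 30.0},
    "ensemble_stats": {"residues": []},
    "bridge": {
        "n_missing": 3,
        "per_bond_span": 3.8,
        "ring_tolerance": 5.0,
        "stack_gap": 6.0,
        "ecd_ct_residue": None,
        "tm_nt_residue": None,
    },
    "membrane": {"thickness": 30.0, "tm_span": None},
    "holo": {
        "enabled": True,
        "hinge_residue": None,
        "domain_span": None,
        "anchor_residue": None,
        "angle_step": 2.0,
        "subdivisions": 2,
    },
}


def _merge_validate(defaults: dict, user: dict, path: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, value in user.items():
        if key not in defaults:
            raise ConfigError(f"unknown configuration key {path + key!r}")
        if isinstance(defaults[key], dict) and isinstance(value, dict):
            out[key] = _merge_validate(defaults[key], value, f"{path}{key}.")
        else:
            out[key] = value
    return out


def load_config(source: dict | str | os.PathLike | None = None) -> dict:
    """Validated configuration: ``source`` may be a mapping, a YAML path, or
    None for the all-fixture default.  Unknown keys are rejected."""
    if source is None:
        user: dict = {}
    elif isinstance(source, dict):
        user = source
    else:
        import yaml

        with open(source) as fh:
            user = yaml.safe_load(fh) or {}
    return _merge_validate(DEFAULT_CONFIG, user)


def _residue_ref(value, numbering: NumberingMap, what: str) -> int:
    """Parse an explicit-scheme residue reference ("171:file") into a file
    number.  Bare integers are rejected: the scheme must be declared."""
    if value is None:
        return None
    if isinstance(value, int):
        raise ConfigError(
            f"{what}: residue reference {value!r} lacks a numbering scheme "
            "(use e.g. '171:precursor')"
        )
    pos_s, _, scheme = str(value).partition(":")
    if not scheme:
        raise ConfigError(f"{what}: residue reference {value!r} lacks a scheme tag")
    from .structure_io import map_numbering

    return map_numbering(int(pos_s), scheme, "file", numbering)


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def run_pipeline(config: dict | None = None, outdir: str | os.PathLike | None = None) -> dict:
    """Run the full workflow and return the JSON-ready summary.

    When ``outdir`` is given, per-stage PDB files, a TSV of assembly metrics
    and ``summary.json`` are written there.  Any stage failure raises
    :class:`StageError` naming the stage; artifacts of completed stages
    remain on disk.
    """
    cfg = load_config(config)
    numbering = NumberingMap(**cfg["numbering"])
    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)
    summary: dict = {
        "schema_version": SUMMARY_SCHEMA_VERSION,
        "package_version": __version__,
        "config": _jsonable(cfg),
        "stages": {},
    }

    def emit(name: str, ensemble_like):
        if outdir is not None:
            write_structure(ensemble_like, os.path.join(outdir, f"{name}.pdb"))

    # ---- stage: inputs -------------------------------------------------
    stage = "inputs"
    try:
        fixture_mode = cfg["inputs"]["kind"] == "fixtures"
        if fixture_mode:
            fx = cfg["fixtures"]
            target, template = make_gapped_pair(
                protein_length=fx["protein_length"],
                deleted_span=tuple(fx["deleted_span"]),
                seed=cfg["seed"],
                fold=fx["fold"],
            )
            bundle = make_c3_bundle(**fx["bundle"])
            tm_ensemble = make_noisy_ensemble(
                bundle, seed=cfg["seed"] + 1, **fx["ensemble"]
            )
            holo_template = None  # built after docking, from the protomer
        elif cfg["inputs"]["kind"] == "files":
            inp = cfg["inputs"]
            if not inp["target"] or not inp["template"]:
                raise ConfigError("files mode requires inputs.target and inputs.template")
            target = read_structure(inp["target"], "first", numbering).conformers[0].protomers[0]
            template = read_structure(inp["template"], "first", numbering).conformers[0].protomers[0]
            tm_ensemble = (
                read_structure(inp["tm_ensemble"], "all", numbering)
                if inp["tm_ensemble"] else None
            )
            holo_template = (
                read_structure(inp["holo_template"], "first", numbering).conformers[0]
                if inp["holo_template"] else None
            )
            bundle = None
        else:
            raise ConfigError(f"unknown inputs.kind {cfg['inputs']['kind']!r}")
        summary["stages"]["inputs"] = {
            "mode": cfg["inputs"]["kind"],
            "target_residues": len(target),
            "template_residues": len(template),
        }
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # ---- stage: completion --------------------------------------------
    stage = "complete"
    try:
        gaps = detect_gaps(target)
        aln = core_align(target, template, **cfg["align"])
        completed = complete_gaps(target, template, aln, gaps,
                                  anchor_k=cfg["complete"]["anchor_k"])
        emit("completed_protomer", Ensemble([Conformer([completed])]))
        summary["stages"]["complete"] = {
            "gaps": [[g.start, g.end] for g in gaps],
            "core_size": aln.n_core,
            "core_rmsd": round(aln.rmsd, 4),
            "grafted_residues": completed.metadata.get("grafted_residues", []),
            "junction_warnings": len(completed.metadata.get("junction_warnings", [])),
            "remaining_gaps": [[g.start, g.end] for g in detect_gaps(completed)],
        }
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # ---- stage: dock ---------------------------------------------------
    stage = "dock"
    try:
        dk = cfg["dock"]
        grid_cfg = {
            k: tuple(v) if isinstance(v, list) else v for k, v in dk["grid"].items()
        }
        dock_input = completed
        if dk["pre_orient"]:
            # canonical frame: principal axis of the protomer along z, as a
            # membrane-bound receptor protomer would be presented
            ca = completed.ca
            centered = ca - ca.mean(axis=0)
            _, evecs = np.linalg.eigh(centered.T @ centered)
            axis = evecs[:, 2]
            rot, _ = Rotation.align_vectors([[0.0, 0.0, 1.0]], [axis])
            R = rot.as_matrix()
            dock_input = completed.with_coordinates(lambda p: R @ (p - ca.mean(axis=0)))
        models = enumerate_c3_poses(
            dock_input, PoseGrid(**grid_cfg), top_k=dk["top_k"],
            contact_shell=dk["contact_shell"], clash_cutoff=dk["clash_cutoff"],
            w_clash=dk["w_clash"],
        )
        if not models:
            raise RuntimeError("docking produced no models (empty grid?)")
        for m in models:
            emit(f"trimer_rank{m.rank}", Ensemble([m.as_conformer()]))
        summary["stages"]["dock"] = {
            "n_models": len(models),
            "scores": [
                {"rank": m.rank, "contacts": m.score.contacts,
                 "clashes": m.score.clashes, "total": m.score.total,
                 "pose": list(m.pose.as_tuple())}
                for m in models
            ],
        }
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # ---- stage: classify ----------------------------------------------
    stage = "classify"
    try:
        cl = cfg["classify"]
        nt = _residue_ref(cl["nt_residue"], numbering, "classify.nt_residue") \
            or int(completed.residue_numbers[0])
        ct = _residue_ref(cl["ct_residue"], numbering, "classify.ct_residue") \
            or int(completed.residue_numbers[-1])
        slab = MembraneSlab(
            outer_z=cfg["membrane"]["thickness"] / 2,
            inner_z=-cfg["membrane"]["thickness"] / 2,
        )
        rows = []
        for m in models:
            tc = classify_termini(m, nt, ct, threshold=cl["threshold"])
            spans = interface_residues(m, cutoff=dk["contact_shell"])
            rows.append({
                "rank": m.rank,
                "score": m.score.total,
                "nt_ring": round(tc.nt_ring, 2),
                "ct_ring": round(tc.ct_ring, 2),
                "class": tc.label,
                "tilt_deg": round(tilt_angle(m.protomers[0], slab), 1),
                "interface_spans": [[s.start, s.end] for s in spans[0]],
            })
        summary["stages"]["classify"] = {
            "nt_residue": nt, "ct_residue": ct,
            "threshold": cl["threshold"], "models": rows,
        }
        if outdir is not None:
            import pandas as pd

            pd.DataFrame(
                [{k: v for k, v in r.items() if k != "interface_spans"} for r in rows]
            ).to_csv(os.path.join(outdir, "assembly_metrics.tsv"), sep="\t", index=False)
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # ---- stage: ensemble stats ----------------------------------------
    stage = "ensemble-stats"
    try:
        if tm_ensemble is not None:
            residues = cfg["ensemble_stats"]["residues"]
            if not residues and fixture_mode:
                nums = bundle.protomers[0].residue_numbers
                residues = [f"{int(nums[0])}:file", f"{int(nums[len(nums)//2])}:file",
                            f"{int(nums[-1])}:file"]
            stats = {}
            for ref in residues:
                num = _residue_ref(ref, numbering, "ensemble_stats.residues")
                rs = ensemble_ring_stats(tm_ensemble, num)
                stats[str(ref)] = {"mean": round(rs.mean, 3), "sd": round(rs.sd, 3),
                                   "n_conformers": len(rs.per_conformer)}
            summary["stages"]["ensemble_stats"] = stats
        else:
            summary["stages"]["ensemble_stats"] = {"skipped": "no TM ensemble input"}
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # ---- stage: bridge -------------------------------------------------
    stage = "bridge"
    try:
        br = cfg["bridge"]
        ct_res = _residue_ref(br["ecd_ct_residue"], numbering, "bridge.ecd_ct_residue") \
            or int(completed.residue_numbers[-1])
        if fixture_mode:
            tm_nt_res = int(bundle.protomers[0].residue_numbers[0])
            tm_trimer = bundle
        elif tm_ensemble is not None:
            tm_nt_res = _residue_ref(br["tm_nt_residue"], numbering, "bridge.tm_nt_residue")
            if tm_nt_res is None:
                raise ConfigError("bridge.tm_nt_residue required in files mode")
            tm_trimer = tm_ensemble.conformers[0]
        else:
            tm_trimer = None
        if tm_trimer is not None:
            if tm_ensemble is not None:
                tm_nt_ring = ensemble_ring_stats(tm_ensemble, tm_nt_res).mean
            else:
                tm_nt_ring = ring_distance(tm_trimer, tm_nt_res)
            # among the ranked candidates, select the one whose
            # membrane-proximal ring best matches the TM bundle ring — the
            # geometric selection rule for the membrane-compatible model
            best = min(
                models,
                key=lambda m: abs(ring_distance(m, ct_res) - float(tm_nt_ring)),
            )
            ecd_ct_ring = ring_distance(best, ct_res)
            compat = ring_compatibility(ecd_ct_ring, float(tm_nt_ring),
                                        tolerance=br["ring_tolerance"])
            # stack the ECD trimer coaxially above the TM rings and measure
            # the per-protomer anchor separation the missing linker must span
            ecd_anchor = best.protomers[0].ca_of(ct_res)
            tm_anchor = tm_trimer.protomers[0].ca_of(tm_nt_res)
            radial_ecd = float(np.linalg.norm(ecd_anchor[:2]))
            radial_tm = float(np.linalg.norm(tm_anchor[:2]))
            verdict = linker_bridge_feasible(
                br["n_missing"],
                np.array([radial_ecd, 0.0, br["stack_gap"]]),
                np.array([radial_tm, 0.0, 0.0]),
                per_bond_span=br["per_bond_span"],
            )
            summary["stages"]["bridge"] = {
                "selected_rank": best.rank,
                "ecd_ct_residue": ct_res,
                "tm_nt_residue": tm_nt_res,
                "ecd_ct_ring": round(ecd_ct_ring, 2),
                "tm_nt_ring": round(float(tm_nt_ring), 2),
                "ring_compatible": compat.compatible,
                "ring_mismatch": round(compat.mismatch, 2),
                "n_missing": br["n_missing"],
                "required_span": round(verdict.required_span, 2),
                "max_span": round(verdict.max_span, 2),
                "feasible": verdict.feasible,
                "slack": round(verdict.slack, 2),
            }
        else:
            best = models[0]
            summary["stages"]["bridge"] = {"skipped": "no TM input"}
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # ---- stage: holo ---------------------------------------------------
    stage = "holo"
    try:
        ho = cfg["holo"]
        if not ho["enabled"]:
            summary["stages"]["holo"] = {"skipped": "disabled"}
        else:
            if fixture_mode:
                # splayed ligand-bound arrangement of the same fold: copies
                # tilted outward on a wide ring
                from .assembly import PoseParams, replicate_c3

                fx = cfg["fixtures"]
                splayed = replicate_c3(
                    template,
                    PoseParams(euler=(0.0, fx["holo_splay_tilt"], 0.0),
                               radial_offset=fx["holo_ring_radius"]),
                )
                holo_template = splayed.as_conformer()
                receptor_chains = ("A", "B", "C")
            else:
                if holo_template is None:
                    summary["stages"]["holo"] = {"skipped": "no holo template input"}
                    raise _SkipStage
                receptor_chains = tuple(cfg["inputs"]["holo_receptor_chains"] or ())
                if len(receptor_chains) != 3:
                    raise ConfigError(
                        "inputs.holo_receptor_chains must name 3 chains in files mode"
                    )
            holo = place_on_template(completed, holo_template, receptor_chains,
                                     seed_mapping=cfg["align"]["seed_mapping"],
                                     trim_cutoff=cfg["align"]["trim_cutoff"])
            emit("holo_assembly", Ensemble([holo.as_conformer()]))
            holo_ct_ring = ring_distance(holo, ct_res)
            holo_required = None
            holo_verdict = None
            if tm_trimer is not None:
                radial_holo = np.linalg.norm(holo.protomers[0].ca_of(ct_res)[:2])
                radial_tm = np.linalg.norm(tm_trimer.protomers[0].ca_of(tm_nt_res)[:2])
                holo_verdict = linker_bridge_feasible(
                    br["n_missing"],
                    np.array([radial_holo, 0.0, br["stack_gap"]]),
                    np.array([radial_tm, 0.0, 0.0]),
                    per_bond_span=br["per_bond_span"],
                )
                holo_required = holo_verdict.required_span
            hinge_res = _residue_ref(ho["hinge_residue"], numbering, "holo.hinge_residue")
            if hinge_res is None:
                nums = completed.residue_numbers
                hinge_res = int(nums[int(len(nums) * 0.7)])
            dom = (
                parse_span(ho["domain_span"]).in_scheme("file", numbering)
                if ho["domain_span"]
                else RegionSpan(hinge_res + 1, int(completed.residue_numbers[-1]), "file")
            )
            anchor = _residue_ref(ho["anchor_residue"], numbering, "holo.anchor_residue") \
                or int(completed.residue_numbers[-1])
            if tm_trimer is not None:
                target_pt = tm_trimer.protomers[0].ca_of(tm_nt_res)
            else:
                target_pt = holo.protomers[0].ca.mean(axis=0)
            moved, move, achieved = hinge_rotate(
                holo.protomers[0],
                HingeSearch(hinge_res, dom, subdivisions=ho["subdivisions"],
                            angle_step=ho["angle_step"]),
                target_pt, anchor,
            )
            initial = float(np.linalg.norm(holo.protomers[0].ca_of(anchor) - target_pt))
            summary["stages"]["holo"] = {
                "per_copy_rmsd": [round(r, 3) for r in holo.metadata["per_copy_rmsd"]],
                "ct_ring": round(holo_ct_ring, 2),
                "required_span": round(holo_required, 2) if holo_required is not None else None,
                "feasible": holo_verdict.feasible if holo_verdict else None,
                "hinge_residue": hinge_res,
                "hinge_angle": move.angle,
                "hinge_axis": [round(x, 4) for x in move.axis],
                "anchor_initial_distance": round(initial, 2),
                "anchor_achieved_distance": round(achieved, 2),
            }
    except _SkipStage:
        pass
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    if outdir is not None:
        with open(os.path.join(outdir, "summary.json"), "w") as fh:
            json.dump(_jsonable(summary), fh, indent=2, sort_keys=True)
        with open(os.path.join(outdir, "pipeline.log"), "w") as fh:
            fh.write(f"trisym {__version__}\n")
            fh.write(json.dumps(_jsonable(cfg), indent=2, sort_keys=True) + "\n")
    return _jsonable(summary)


class _SkipStage(Exception):
    pass
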