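"""End-to-end orchestration: simulate -> semantics -> per-subject HMMs ->
linkage -> dwell statistics -> group PLS -> report.

Every stage writes its artifacts under the output directory and the run
closes with a manifest (config, seeds, package version, content hashes);
rerunning with an identical config and seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import annotations as ann
from . import grouplevel, linkage, prep, synthetic, temporal, text
from ._utils import spawn_seeds, write_tsv
from .hmm import hard_assign, multi_restart_fit

logger = logging.getLogger(__name__)

N_PC = 3  # limbic PCs per hemisphere


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Settings for one full run."""

    out_dir: str = "nbstates_out"
    seed: int = 0
    tr_seconds: float = 2.0
    window_minutes: float = 4.0
    s: int = 200  # semantic contexts
    n_states: int = 4
    n_restarts: int = 100
    permutation_B: int = 1000
    cv_folds: int = 20
    nmf_max_iter: int = 500
    pls_network: str | None = None  # default: last (most associative) network
    generator: dict = field(default_factory=dict)  # GeneratorConfig overrides

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)

    def demo(self) -> "PipelineConfig":
        """Desk-scale settings for a quick smoke run."""
        gen = {
            "n_subjects": 3,
            "n_timepoints": 400,
            "networks": [("NETA", 6), ("NETB", 8)],
            "limbic": {"HC": 8, "AM": 5},
            "n_episodes": 30,
        }
        gen.update(self.generator)
        return PipelineConfig(
            out_dir=self.out_dir,
            seed=self.seed,
            tr_seconds=self.tr_seconds,
            window_minutes=self.window_minutes,
            s=min(self.s, 20),
            n_states=self.n_states,
            n_restarts=min(self.n_restarts, 3),
            permutation_B=min(self.permutation_B, 200),
            cv_folds=min(self.cv_folds, 5),
            nmf_max_iter=min(self.nmf_max_iter, 200),
            pls_network=self.pls_network,
            generator=gen,
        )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns the in-memory results bundle."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"config": asdict(config)}
    stage = "simulate"
    try:
        gen_overrides = dict(config.generator)
        gen_overrides.setdefault("seed", config.seed)
        gen_overrides.setdefault("tr_seconds", config.tr_seconds)
        gen_overrides.setdefault("n_states", config.n_states)
        gen_overrides.setdefault("smoothing_window_minutes", config.window_minutes)
        if "networks" in gen_overrides:
            gen_overrides["networks"] = [
                (str(n), int(r)) for n, r in gen_overrides["networks"]
            ]
        gcfg = synthetic.GeneratorConfig(**gen_overrides)
        gt = synthetic.generate_ground_truth(gcfg)
        data_dir = out / "data"
        synthetic.write_outputs(gt, data_dir, seed=config.seed)
        subjects = [
            synthetic.simulate_subject_timeseries(gt, i, seed=config.seed)
            for i in range(gcfg.n_subjects)
        ]
        T = gcfg.n_timepoints
        segment_bounds = gt.segment_bounds
        bundle["ground_truth"] = gt

        stage = "semantics"
        srt_text = (data_dir / "subtitles.srt").read_text()
        timeline = text.preprocess_tokens(
            text.parse_timed_text(srt_text, config.tr_seconds, T)
        )
        counts = text.build_word_count_matrix(timeline)
        smoothed = text.smooth_counts(counts, config.window_minutes, config.tr_seconds)
        weighted = text.tfidf_transform(smoothed, occupancy_from=counts)
        s_eff = min(config.s, min(weighted.values.shape))
        contexts = text.fit_nmf_lsa(
            weighted, s=s_eff, seed=config.seed, max_iter=config.nmf_max_iter
        )
        text.serialize_contexts(contexts, out / "semantics")
        bundle["contexts"] = contexts

        stage = "annotations"
        intervals = ann.read_intervals_tsv(data_dir / "observer_intervals.tsv")
        attributes, kinds, categories = gt.attribute_set
        desc = ann.build_description_matrix(
            intervals,
            n_observers=gcfg.n_observers,
            T=T,
            tr_seconds=config.tr_seconds,
            attributes=attributes,
            kinds=kinds,
            categories=categories,
            emotion_labels=synthetic.EMOTION_LABELS,
            passthrough=gt.passthrough,
        )
        write_tsv(desc.to_frame(), out / "annotations.tsv")
        (out / "annotations_meta.json").write_text(
            json.dumps(
                {"kinds": kinds, "categories": categories}, indent=2, sort_keys=True
            )
        )
        bundle["annotations"] = desc

        stage = "hmm"
        combos = gt.combinations
        seeds = spawn_seeds(config.seed, gcfg.n_subjects * len(combos))
        meta = subjects[0].region_meta
        solutions: dict = {}
        pca_models: dict = {}
        combo_labels: dict = {}
        for i, sub in enumerate(subjects):
            std = prep.segmentwise_standardize(
                sub.table.to_numpy(dtype=float), segment_bounds
            )
            std_df = pd.DataFrame(std, columns=sub.table.columns)
            embeds = {}
            for structure in gcfg.limbic:
                cols_l = meta[
                    (meta.structure == structure) & (meta.hemisphere == "L")
                ].subregion_id
                cols_r = meta[
                    (meta.structure == structure) & (meta.hemisphere == "R")
                ].subregion_id
                model, emb = prep.fit_limbic_pca(
                    std_df[cols_l].to_numpy(), std_df[cols_r].to_numpy(), n_pc=N_PC
                )
                embeds[structure] = emb
                pca_models[(i, structure)] = model
            for ci, (network, structure) in enumerate(combos):
                parcel_cols = list(meta[meta.network == network].subregion_id)
                labels = parcel_cols + [
                    f"{structure}_{h}_PC{j + 1}" for h in "LR" for j in range(N_PC)
                ]
                combo = prep.assemble_combination(
                    std_df[parcel_cols].to_numpy(),
                    embeds[structure],
                    labels,
                    subject_id=i,
                    network=network,
                    limbic_structure=structure,
                )
                combo_labels[(network, structure)] = labels
                sol = multi_restart_fit(
                    combo.values,
                    config.n_states,
                    contexts.W,
                    n_restarts=config.n_restarts,
                    seed=seeds[i * len(combos) + ci],
                )
                solutions[(i, (network, structure))] = (sol, combo)
        bundle["solutions"] = solutions
        bundle["pca_models"] = pca_models

        stage = "linkage"
        link_rows = []
        perm_seeds = spawn_seeds(config.seed + 1, len(solutions))
        for j, ((i, combo_key), (sol, _)) in enumerate(sorted(solutions.items())):
            profile = linkage.linkage_profile(
                sol.gamma,
                contexts.W,
                annotations=desc.values,
                B=config.permutation_B,
                seed=perm_seeds[j],
            )
            link_rows.append(
                {
                    "subject": i,
                    "network": combo_key[0],
                    "structure": combo_key[1],
                    "link_index": profile.model_link_index,
                    "permutation_p": profile.permutation_p,
                }
            )
        link_table = pd.DataFrame(link_rows)
        write_tsv(link_table, out / "linkage.tsv")
        bundle["link_table"] = link_table
        per_network = (
            link_table.groupby(["subject", "network"])["link_index"]
            .mean()
            .unstack("network")
        )
        ref_net = config.pls_network or gcfg.networks[-1][0]
        if per_network.shape[0] >= 2 and per_network.shape[1] >= 2:
            bundle["network_tests"] = linkage.compare_networks(per_network, ref_net)
            write_tsv(bundle["network_tests"], out / "network_tests.tsv")

        stage = "temporal"
        dwell = temporal.group_dwell_table(
            {
                (i, f"{net}&{structure}"): v[0]
                for (i, (net, structure)), v in solutions.items()
            },
            segment_bounds,
            config.tr_seconds,
        )
        write_tsv(dwell, out / "dwell.tsv")
        bundle["dwell_table"] = dwell

        stage = "group_pls"
        pls_combo = (ref_net, next(iter(gcfg.limbic)))
        template_sol = solutions[(0, pls_combo)][0]
        per_subject_G, per_subject_E = [], []
        for i in range(gcfg.n_subjects):
            sol, combo = solutions[(i, pls_combo)]
            aligned = (
                sol
                if i == 0
                else grouplevel.apply_alignment(
                    sol, grouplevel.align_states(template_sol, sol)
                )
            )
            seq = hard_assign(aligned.gamma)
            E_full = np.hstack([contexts.W, desc.values])
            per_subject_G.append(grouplevel.partition_by_state(seq, combo.values))
            per_subject_E.append(grouplevel.partition_by_state(seq, E_full))
        G_k, subj_labels = grouplevel.concat_group(per_subject_G)
        E_k, _ = grouplevel.concat_group(per_subject_E)
        signatures = []
        for k in range(config.n_states):
            if G_k[k].shape[0] < 2 * config.cv_folds:
                logger.warning("state %d has too few rows for PLS; skipped", k)
                continue
            sig = grouplevel.fit_pls1(E_k[k], G_k[k], state=k)
            rs, mean_r = grouplevel.crossval_pls(
                E_k[k], G_k[k], subj_labels[k], n_folds=config.cv_folds,
                seed=config.seed,
            )
            sig.cv_correlations = rs
            sig.cv_mean = mean_r
            pca = pca_models[(0, pls_combo[1])]
            r_net = len(combo_labels[pls_combo]) - 2 * N_PC
            sig.extras["report"] = grouplevel.signature_report(
                sig,
                contexts=contexts,
                annotation_names=attributes,
                annotation_categories=categories,
                n_semantic=contexts.s,
                pca_models={pls_combo[1]: pca},
                limbic_slices={pls_combo[1]: slice(r_net, r_net + 2 * N_PC)},
                brain_labels=combo_labels[pls_combo],
            )
            signatures.append(sig)
        bundle["signatures"] = signatures
        sig_json = [
            {
                "state": s.state,
                "cv_mean": s.cv_mean,
                "cv_correlations": [float(x) for x in s.cv_correlations],
                "train_correlation": s.train_correlation,
                "report": s.extras.get("report"),
            }
            for s in signatures
        ]
        (out / "group_signatures.json").write_text(
            json.dumps(sig_json, indent=2, sort_keys=True)
        )

        stage = "report"
        report = write_report(bundle)
        (out / "report.md").write_text(report)
        cfg_echo = asdict(config)
        cfg_echo.pop("out_dir")  # implied by the manifest's own location
        manifest = {
            "version": __version__,
            "config": cfg_echo,
            "seed": config.seed,
            "files": {
                str(p.relative_to(out)): _sha256(p)
                for p in sorted(out.rglob("*"))
                if p.is_file() and p.name != "manifest.json"
            },
        }
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True)
        )
        bundle["manifest"] = manifest
        return bundle
    except StageError:
        raise
    except Exception as exc:
        written = sorted(str(p.relative_to(out)) for p in out.rglob("*") if p.is_file())
        logger.error("stage %r failed; artifacts so far: %s", stage, written)
        raise StageError(stage, exc) from exc


def write_report(bundle: dict) -> str:
    """Human-readable markdown summary mirroring the analysis tables."""
    missing = [
        k for k in ("link_table", "dwell_table", "signatures") if k not in bundle
    ]
    if missing:
        raise ValueError(f"incomplete bundle, missing: {missing}")
    link = bundle["link_table"]
    dwell = bundle["dwell_table"]
    lines = ["# Dynamic brain-state analysis report", ""]
    lines.append("## Semantics-brain link strength (median across subjects)")
    lines.append("")
    med = (
        link.groupby(["network", "structure"])["link_index"]
        .median()
        .sort_values(ascending=False)
    )
    lines.append("| network | structure | median link r |")
    lines.append("|---|---|---|")
    for (net, structure), v in med.items():
        lines.append(f"| {net} | {structure} | {v:.4f} |")
    lines.append("")
    lines.append("## Dwell-time summary (mean across subjects)")
    lines.append("")
    lines.append("| combination | mean dwell (s) | sd (s) | volatility (s) |")
    lines.append("|---|---|---|---|")
    grp = dwell.groupby("combination")[["mean_dwell_s", "sd_dwell_s", "volatility_s"]]
    for combo, row in grp.mean().iterrows():
        lines.append(
            f"| {combo} | {row.mean_dwell_s:.2f} | {row.sd_dwell_s:.2f} | "
            f"{row.volatility_s:.2f} |"
        )
    lines.append("")
    lines.append("## Group PLS signatures")
    lines.append("")
    lines.append("| state | train r | CV mean r |")
    lines.append("|---|---|---|")
    for s in bundle["signatures"]:
        lines.append(f"| {s.state} | {s.train_correlation:.4f} | {s.cv_mean:.4f} |")
    lines.append("")
    return "\n".join(lines)
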