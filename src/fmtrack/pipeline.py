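"""End-to-end orchestration: filter -> rarefy -> engraftment -> diversity -> ANCOM.

A single seed deterministically derives independent substreams for each
stochastic stage (rarefaction, PERMANOVA permutations), so a rerun with the
same inputs and seed reproduces every output file byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from skbio import TreeNode

from . import diversity, engraftment
from .differential import AncomConfig, ancom, volcano_table
from .tables import (
    FilterConfig,
    RarefactionConfig,
    SampleMeta,
    Taxonomy,
    prevalence_filter,
    rarefy,
    read_count_table,
    write_count_table,
)

log = logging.getLogger("fmtrack")

__all__ = ["RunConfig", "RunReport", "run_pipeline", "worked_example"]


@dataclass(frozen=True)
class RunConfig:
    counts_path: Path
    taxonomy_path: Path
    metadata_path: Path
    tree_path: Path | None
    output_dir: Path
    seed: int = 0
    filter_cfg: FilterConfig = field(default_factory=FilterConfig)
    rarefaction_depth: int = 16639
    transfer_cfg: engraftment.TransferConfig = field(default_factory=engraftment.TransferConfig)
    ancom_cfg: AncomConfig = field(default_factory=AncomConfig)
    run_beta: bool = True
    n_permutations: int = 999

    def validate(self) -> None:
        for name in ("counts_path", "taxonomy_path", "metadata_path"):
            path = getattr(self, name)
            if not Path(path).exists():
                raise FileNotFoundError(f"{name} does not exist: {path}")
        if self.run_beta:
            if self.tree_path is None or not Path(self.tree_path).exists():
                raise FileNotFoundError(
                    f"beta diversity enabled but tree_path missing: {self.tree_path}"
                )


@dataclass
class RunReport:
    parameters: dict
    input_checksums: dict[str, str]
    produced_files: dict[str, str]  # path -> sha256
    headline: dict

    def to_json(self) -> str:
        return json.dumps(
            {
                "parameters": self.parameters,
                "input_checksums": self.input_checksums,
                "produced_files": self.produced_files,
                "headline": self.headline,
            },
            indent=2,
            sort_keys=True,
            default=str,
        )


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(cfg: RunConfig) -> RunReport:
    """Run every analysis stage on the configured inputs.

    Validation happens before any computation; a failure in one stage
    raises with the stage named, leaving outputs of earlier stages intact.
    """
    cfg.validate()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    produced: dict[str, str] = {}
    headline: dict = {}
    root_ss = np.random.SeedSequence(cfg.seed)
    stage_seeds = {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(("rarefy", "permanova"), root_ss.spawn(2))
    }
    log.info("stage seeds: %s", stage_seeds)

    def emit(name: str, writer) -> Path:
        path = out / name
        writer(path)
        produced[str(path)] = _sha256(path)
        return path

    stage = "load"
    try:
        table = read_count_table(cfg.counts_path)
        tax = Taxonomy.read_tsv(cfg.taxonomy_path)
        meta = SampleMeta.read_tsv(cfg.metadata_path)
        meta.validate_covers(table)

        stage = "filter"
        filtered = prevalence_filter(table, meta, cfg.filter_cfg)
        emit("counts_filtered.tsv", lambda p: write_count_table(filtered, p))

        stage = "rarefy"
        rcfg = RarefactionConfig(depth=cfg.rarefaction_depth, seed=stage_seeds["rarefy"])
        rarefied = rarefy(filtered, rcfg)
        emit("counts_rarefied.tsv", lambda p: write_count_table(rarefied, p))

        stage = "engraftment"
        timepoints = [t for t in meta.recipient_timepoints() if t not in ("D-1", "D0")]
        for group in meta.groups():
            donor_id = meta.donor_sample(group)
            baseline_ids = meta.recipient_samples(group, "D-1")
            cls = engraftment.classify_sources(
                filtered.select_samples([donor_id]),
                filtered.select_samples(baseline_ids),
                cfg.transfer_cfg.presence,
            )
            slices = {
                tp: filtered.select_samples(meta.recipient_samples(group, tp))
                for tp in timepoints
            }
            summary = engraftment.detect_transfers(cls, slices, cfg.transfer_cfg)
            emit(f"transfers_{group}.tsv", lambda p, s=summary: s.to_frame().to_csv(p, sep="\t"))
            last = timepoints[-1]
            fam = engraftment.family_transfer_rates(cls, summary, tax, last)
            emit(f"family_rates_{group}_{last}.tsv", lambda p, f=fam: f.to_csv(p, sep="\t"))
            n_donor = len(cls.donor_present)
            n_moved = len(summary.donor_only_transferred[last])
            headline[f"{group}_donor_only_transferred_{last}"] = n_moved
            headline[f"{group}_transfer_rate_pct_{last}"] = engraftment.transfer_rate(
                n_moved, n_donor
            )

        groups = meta.groups()
        if len(groups) == 2:
            d_a = meta.donor_sample(groups[0])
            d_b = meta.donor_sample(groups[1])
            base_union = set()
            for g in groups:
                for s in meta.recipient_samples(g, "D-1"):
                    base_union.add(s)
            present = filtered.data >= cfg.transfer_cfg.presence.min_count
            set_a = frozenset(present.columns[present.loc[d_a]])
            set_b = frozenset(present.columns[present.loc[d_b]])
            set_c = frozenset(present.columns[present.loc[sorted(base_union)].any(axis=0)])
            venn = engraftment.venn_decomposition(set_a, set_b, set_c)
            emit(
                "venn_regions.tsv",
                lambda p: pd.Series(venn, name="count").rename_axis("region").to_csv(p, sep="\t"),
            )

        stage = "alpha_diversity"
        alpha = diversity.alpha_diversity(rarefied)
        emit("alpha_diversity.tsv", lambda p: alpha.to_csv(p, sep="\t"))
        recipient_tp = [t for t in meta.recipient_timepoints()]
        tests = []
        if len(groups) == 2:
            for tp in recipient_tp:
                ids_a = [s for s in meta.recipient_samples(groups[0], tp) if s in alpha.index]
                ids_b = [s for s in meta.recipient_samples(groups[1], tp) if s in alpha.index]
                if len(ids_a) < 3 or len(ids_b) < 3:
                    continue
                for metric in ("observed_asvs", "shannon", "simpson"):
                    res = diversity.compare_alpha(alpha.loc[ids_a, metric], alpha.loc[ids_b, metric])
                    tests.append(
                        {"timepoint": tp, "metric": metric, "test": res.test,
                         "statistic": res.statistic, "p_value": res.p_value}
                    )
        if tests:
            emit(
                "alpha_group_tests.tsv",
                lambda p: pd.DataFrame(tests).to_csv(p, sep="\t", index=False),
            )

        if cfg.run_beta:
            stage = "beta_diversity"
            tree = TreeNode.read(str(cfg.tree_path))
            rel_samples = [s for s in filtered.sample_ids if filtered.depths()[s] > 0]
            beta_table = filtered.select_samples(rel_samples)
            dm = diversity.weighted_unifrac(beta_table, tree)
            emit(
                "weighted_unifrac.tsv",
                lambda p: pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids)
                .rename_axis("sample_id")
                .to_csv(p, sep="\t"),
            )
            ord_res = diversity.pcoa(dm)
            emit(
                "pcoa_coordinates.tsv",
                lambda p: _write_pcoa(ord_res, p),
            )

            stage = "permanova"
            rec_ids = [s for s in dm.ids if meta.data.loc[s, "role"] == "recipient"]
            labels = [meta.data.loc[s, "timepoint"] for s in rec_ids]
            sub_dm = dm.filter(rec_ids)
            res = diversity.permanova(
                sub_dm, labels, n_perm=cfg.n_permutations, seed=stage_seeds["permanova"]
            )
            headline["permanova_timepoints"] = {
                "pseudo_F": res.pseudo_f, "R2": res.r_squared, "p_value": res.p_value,
                "n_permutations": res.n_permutations,
            }
            emit(
                "permanova.tsv",
                lambda p: pd.DataFrame([headline["permanova_timepoints"]]).to_csv(
                    p, sep="\t", index=False
                ),
            )

        stage = "ancom"
        if len(groups) == 2:
            n_sig = {}
            for tp in [t for t in recipient_tp if t != "D0"]:
                ids_a = meta.recipient_samples(groups[0], tp)
                ids_b = meta.recipient_samples(groups[1], tp)
                ids_a = [s for s in ids_a if s in filtered.sample_ids]
                ids_b = [s for s in ids_b if s in filtered.sample_ids]
                if len(ids_a) < 3 or len(ids_b) < 3:
                    continue
                sub = filtered.select_samples(ids_a + ids_b)
                labels = [groups[0]] * len(ids_a) + [groups[1]] * len(ids_b)
                res = ancom(sub, labels, cfg.ancom_cfg)
                emit(
                    f"ancom_{tp}.tsv",
                    lambda p, r=res: volcano_table(r).to_csv(p, sep="\t"),
                )
                n_sig[tp] = len(res.significant)
            headline["ancom_significant_asvs"] = n_sig
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    report = RunReport(
        parameters={
            "seed": cfg.seed,
            "stage_seeds": stage_seeds,
            "filter": {"min_count": cfg.filter_cfg.min_count,
                       "min_sample_fraction": cfg.filter_cfg.min_sample_fraction},
            "rarefaction_depth": cfg.rarefaction_depth,
            "recipient_prevalence": cfg.transfer_cfg.recipient_prevalence,
            "ancom": {"cutoff": cfg.ancom_cfg.w_ratio_cutoff,
                      "alpha": cfg.ancom_cfg.per_ratio_alpha},
            "n_permutations": cfg.n_permutations,
        },
        input_checksums={
            str(p): _sha256(p)
            for p in (cfg.counts_path, cfg.taxonomy_path, cfg.metadata_path)
        }
        | ({str(cfg.tree_path): _sha256(cfg.tree_path)} if cfg.run_beta else {}),
        produced_files=produced,
        headline=headline,
    )
    (out / "report.json").write_text(report.to_json())
    return report


def _write_pcoa(result, path: Path) -> None:
    with open(path, "w") as fh:
        explained = "\t".join(f"{x:.6f}" for x in result.proportion_explained)
        fh.write(f"# proportion_explained\t{explained}\n")
        result.coordinates.to_csv(fh, sep="\t")


#: printed worked examples: (transferred, donor_total) -> percent
WORKED_EXAMPLES: Mapping[str, tuple[int, int, float]] = {
    "rygb_donor_d16": (132, 415, 31.8),
    "sham_donor_d16": (41, 379, 10.8),
    "bacteroidaceae_rygb_d16": (8, 11, 72.7),
    "ruminococcaceae_rygb_d16": (35, 90, 38.9),
    "rikenellaceae_sham_d16": (3, 6, 50.0),
    "ruminococcaceae_sham_d16": (15, 109, 13.8),
}


def worked_example() -> pd.DataFrame:
    """Recompute the packaged transfer-rate worked examples.

    Each row gives the transferred / donor-total pair, the percentage the
    package computes, and the expected percentage; computed and expected
    agree to the printed decimal.
    """
    rows = []
    for name, (k, n, expected) in WORKED_EXAMPLES.items():
        got = engraftment.transfer_rate(k, n)
        rows.append(
            {"case": name, "transferred": k, "donor_total": n,
             "computed_pct": got, "expected_pct": expected, "match": got == expected}
        )
    return pd.DataFrame(rows).set_index("case")
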