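"""Synthetic FMT experiments with known engraftment ground truth.

Emulates the statistical structure of a two-donor / two-recipient-group rat
FMT study: one pooled donor per group (a Proteobacteria-rich community for
the gastric-bypass group, a conventional one for the sham group), recipient
baselines, a broad-spectrum antibiotic knockdown, and a post-transplant
time course in which a configurable subset of donor ASVs engrafts, with
optional washout (transient colonisation).  Communities are drawn from a
Dirichlet-multinomial: within each family, ASV proportions follow a
Dirichlet whose total concentration controls heterogeneity, rescaled to the
family's target relative abundance; reads are multinomial at a random
sequencing depth.

The generator's record of which ASVs truly engraft, when, and at what
carriage probability (:class:`EngraftmentTruth`) is the oracle against
which transfer detection is scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

from .tables import CountTable, SampleMeta, Taxonomy, _day_number

__all__ = [
    "FamilySpec",
    "CommunitySpec",
    "ExperimentDesign",
    "EngraftmentTruth",
    "FmtExperiment",
    "rygb_donor_spec",
    "sham_donor_spec",
    "recipient_baseline_spec",
    "generate_donor",
    "generate_experiment",
    "generate_tree",
]


@dataclass(frozen=True)
class FamilySpec:
    """One family block of a community: richness and target relative abundance."""

    name: str
    phylum: str
    n_asvs: int
    proportion: float

    def __post_init__(self) -> None:
        if self.n_asvs < 1:
            raise ValueError(f"family {self.name}: n_asvs must be >= 1")
        if not (0 <= self.proportion <= 1):
            raise ValueError(f"family {self.name}: proportion must be in [0, 1]")


# class/order placeholders per phylum for the 7-rank lineages
_PHYLUM_LINEAGE = {
    "Proteobacteria": ("Gammaproteobacteria", "Enterobacterales"),
    "Bacteroidetes": ("Bacteroidia", "Bacteroidales"),
    "Firmicutes": ("Clostridia", "Clostridiales"),
    "Verrucomicrobia": ("Verrucomicrobiae", "Verrucomicrobiales"),
}


@dataclass(frozen=True)
class CommunitySpec:
    """Family-structured community: targets, richness and Dirichlet concentration."""

    name: str
    families: tuple[FamilySpec, ...]
    concentration: float = 50.0

    def __post_init__(self) -> None:
        total = sum(f.proportion for f in self.families)
        if total > 1 + 1e-9:
            raise ValueError(f"family proportions sum to {total:.4f} > 1")
        names = [f.name for f in self.families]
        if len(names) != len(set(names)):
            raise ValueError("duplicate family names in community spec")

    @property
    def richness(self) -> int:
        return sum(f.n_asvs for f in self.families)

    def effective_proportions(self) -> dict[str, float]:
        """Family targets with any shortfall from 1 spread over the
        Firmicutes/Bacteroidetes bulk, proportionally."""
        total = sum(f.proportion for f in self.families)
        props = {f.name: f.proportion for f in self.families}
        remainder = 1.0 - total
        if remainder > 1e-9:
            bulk = [f for f in self.families if f.phylum in ("Firmicutes", "Bacteroidetes")]
            if not bulk:
                raise ValueError("remainder > 0 but no Firmicutes/Bacteroidetes bulk family")
            bulk_total = sum(f.proportion for f in bulk)
            for f in bulk:
                share = f.proportion / bulk_total if bulk_total > 0 else 1 / len(bulk)
                props[f.name] += remainder * share
        return props


def rygb_donor_spec() -> CommunitySpec:
    """Pooled gastric-bypass donor: 415 ASVs, Proteobacteria 22.1% of which
    Enterobacteriaceae 14.2%."""
    fams = (
        FamilySpec("Enterobacteriaceae", "Proteobacteria", 13, 0.142),
        FamilySpec("Desulfovibrionaceae", "Proteobacteria", 4, 0.034),
        FamilySpec("Burkholderiaceae", "Proteobacteria", 10, 0.045),
        FamilySpec("Bacteroidaceae", "Bacteroidetes", 11, 0.085),
        FamilySpec("Rikenellaceae", "Bacteroidetes", 13, 0.030),
        FamilySpec("Muribaculaceae", "Bacteroidetes", 54, 0.110),
        FamilySpec("Tannerellaceae", "Bacteroidetes", 8, 0.020),
        FamilySpec("Prevotellaceae", "Bacteroidetes", 12, 0.025),
        FamilySpec("Marinifilaceae", "Bacteroidetes", 6, 0.010),
        FamilySpec("Ruminococcaceae", "Firmicutes", 90, 0.235),
        FamilySpec("Lachnospiraceae", "Firmicutes", 146, 0.200),
        FamilySpec("Lactobacillaceae", "Firmicutes", 8, 0.020),
        FamilySpec("Erysipelotrichaceae", "Firmicutes", 10, 0.014),
        FamilySpec("Peptostreptococcaceae", "Firmicutes", 8, 0.008),
        FamilySpec("Clostridiaceae_1", "Firmicutes", 12, 0.006),
        FamilySpec("Christensenellaceae", "Firmicutes", 8, 0.006),
        FamilySpec("Akkermansiaceae", "Verrucomicrobia", 2, 0.010),
    )
    return CommunitySpec("RYGB_donor", fams)


def sham_donor_spec() -> CommunitySpec:
    """Pooled sham-surgery donor: 379 ASVs, Proteobacteria 3.6%."""
    fams = (
        FamilySpec("Enterobacteriaceae", "Proteobacteria", 4, 0.006),
        FamilySpec("Desulfovibrionaceae", "Proteobacteria", 3, 0.012),
        FamilySpec("Burkholderiaceae", "Proteobacteria", 8, 0.018),
        FamilySpec("Bacteroidaceae", "Bacteroidetes", 9, 0.060),
        FamilySpec("Rikenellaceae", "Bacteroidetes", 6, 0.020),
        FamilySpec("Muribaculaceae", "Bacteroidetes", 47, 0.130),
        FamilySpec("Tannerellaceae", "Bacteroidetes", 7, 0.020),
        FamilySpec("Prevotellaceae", "Bacteroidetes", 10, 0.030),
        FamilySpec("Ruminococcaceae", "Firmicutes", 109, 0.300),
        FamilySpec("Lachnospiraceae", "Firmicutes", 150, 0.330),
        FamilySpec("Lactobacillaceae", "Firmicutes", 8, 0.030),
        FamilySpec("Erysipelotrichaceae", "Firmicutes", 8, 0.015),
        FamilySpec("Peptostreptococcaceae", "Firmicutes", 6, 0.010),
        FamilySpec("Christensenellaceae", "Firmicutes", 2, 0.004),
        FamilySpec("Akkermansiaceae", "Verrucomicrobia", 2, 0.015),
    )
    return CommunitySpec("SHAM_donor", fams)


def recipient_baseline_spec() -> CommunitySpec:
    """Indigenous recipient community: 158 ASVs, Proteobacteria 0.012%."""
    fams = (
        FamilySpec("Enterobacteriaceae", "Proteobacteria", 1, 0.00012),
        FamilySpec("Bacteroidaceae", "Bacteroidetes", 5, 0.060),
        FamilySpec("Muribaculaceae", "Bacteroidetes", 15, 0.130),
        FamilySpec("Tannerellaceae", "Bacteroidetes", 3, 0.012),
        FamilySpec("Prevotellaceae", "Bacteroidetes", 2, 0.010),
        FamilySpec("Lachnospiraceae", "Firmicutes", 85, 0.400),
        FamilySpec("Ruminococcaceae", "Firmicutes", 32, 0.300),
        FamilySpec("Lactobacillaceae", "Firmicutes", 6, 0.050),
        FamilySpec("Peptostreptococcaceae", "Firmicutes", 4, 0.020),
        FamilySpec("Erysipelotrichaceae", "Firmicutes", 4, 0.015),
        FamilySpec("Akkermansiaceae", "Verrucomicrobia", 1, 0.00288),
    )
    return CommunitySpec("recipient_baseline", fams)


@dataclass(frozen=True)
class ExperimentDesign:
    """Group sizes, timepoints, knockdown and depth settings of the study design."""

    n_rygbr: int = 6
    n_shamr: int = 5
    timepoints: tuple[str, ...] = ("D-1", "D0", "D1", "D3", "D6", "D9", "D16")
    antibiotic_survival: float = 0.1
    bloom_families: Mapping[str, float] = field(
        default_factory=lambda: {"Lactobacillaceae": 5.0}
    )
    depth_range: tuple[int, int] = (20000, 60000)
    recipient_jitter: float = 5000.0  # Dirichlet concentration around the shared pool

    def __post_init__(self) -> None:
        if self.n_rygbr < 1 or self.n_shamr < 1:
            raise ValueError("group sizes must be >= 1")
        days = [_day_number(t) for t in self.timepoints]
        if days != sorted(days):
            raise ValueError("timepoints must be in chronological order")
        if not (0 < self.antibiotic_survival <= 1):
            raise ValueError("antibiotic_survival must be in (0, 1]")

    @property
    def post_fmt_timepoints(self) -> tuple[str, ...]:
        return tuple(t for t in self.timepoints if _day_number(t) >= 1)


class EngraftmentTruth:
    """Per-ASV engraftment record for one donor–recipient pair.

    Columns: ``engrafts`` (bool), ``first_day`` / ``washout_day`` (timepoint
    labels; washout NaN when colonisation persists), ``carriage``
    (per-recipient carriage probability) and ``abundance_scale`` (relative
    abundance an engrafted ASV contributes in a carrying recipient).
    """

    COLUMNS = ("engrafts", "first_day", "washout_day", "carriage", "abundance_scale")

    def __init__(self, data: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in data.columns]
        if missing:
            raise ValueError(f"truth table missing columns: {missing}")
        df = data[list(self.COLUMNS)].copy()
        df.index = df.index.astype(str)
        df.index.name = "asv_id"
        for asv, row in df[df["engrafts"]].iterrows():
            if not (0 <= row["carriage"] <= 1):
                raise ValueError(f"{asv}: carriage must be in [0, 1]")
            if pd.notna(row["washout_day"]) and not (
                _day_number(str(row["first_day"])) < _day_number(str(row["washout_day"]))
            ):
                raise ValueError(f"{asv}: first_day must precede washout_day")
        self._data = df

    @property
    def data(self) -> pd.DataFrame:
        return self._data

    @property
    def engrafting(self) -> frozenset[str]:
        return frozenset(self._data.index[self._data["engrafts"]])

    def active(self, asv: str, timepoint: str) -> bool:
        """Is the ASV colonising (per the truth schedule) at this timepoint?"""
        row = self._data.loc[asv]
        if not row["engrafts"]:
            return False
        day = _day_number(timepoint)
        if day < _day_number(str(row["first_day"])):
            return False
        if pd.notna(row["washout_day"]) and day >= _day_number(str(row["washout_day"])):
            return False
        return True

    def expected_transferred(self, timepoint: str) -> frozenset[str]:
        return frozenset(a for a in self._data.index if self.active(a, timepoint))

    def write_tsv(self, path) -> None:
        self._data.to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path) -> "EngraftmentTruth":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df["engrafts"] = df["engrafts"].astype(bool)
        return cls(df)


@dataclass(frozen=True)
class FmtExperiment:
    """A complete generated experiment: inputs for every analysis stage."""

    counts: CountTable
    meta: SampleMeta
    taxonomy: Taxonomy
    truth: Mapping[str, EngraftmentTruth]  # per recipient group
    tree: TreeNode
    design: ExperimentDesign


# ---------------------------------------------------------------------------
# community draws


def _family_probabilities(
    spec: CommunitySpec, rng: np.random.Generator
) -> tuple[list[str], np.ndarray, dict[str, str]]:
    """Draw ASV probabilities family-by-family; returns ids, probs, family map."""
    targets = spec.effective_proportions()
    ids: list[str] = []
    probs: list[np.ndarray] = []
    fam_of: dict[str, str] = {}
    for fam in spec.families:
        alpha = np.full(fam.n_asvs, spec.concentration / fam.n_asvs)
        within = rng.dirichlet(alpha) if fam.n_asvs > 1 else np.ones(1)
        fam_ids = [f"{fam.name}_{k:04d}" for k in range(fam.n_asvs)]
        ids.extend(fam_ids)
        probs.append(within * targets[fam.name])
        fam_of.update({i: fam.name for i in fam_ids})
    p = np.concatenate(probs)
    return ids, p / p.sum(), fam_of


def _taxonomy_for(fam_of: Mapping[str, str], phylum_of: Mapping[str, str]) -> Taxonomy:
    rows = {}
    for asv, fam in fam_of.items():
        phylum = phylum_of[fam]
        klass, order = _PHYLUM_LINEAGE.get(phylum, ("Unclassified", "Unclassified"))
        rows[asv] = ["Bacteria", phylum, klass, order, fam, "", ""]
    df = pd.DataFrame.from_dict(
        rows, orient="index",
        columns=["kingdom", "phylum", "class", "order", "family", "genus", "species"],
    )
    return Taxonomy(df)


def generate_donor(
    spec: CommunitySpec, seed: int, depth: int | None = None
) -> tuple[CountTable, Taxonomy]:
    """One pooled donor sample drawn from a community spec.

    ``depth`` fixes the sequencing depth; by default it is drawn uniformly
    from 20,000–60,000 reads.
    """
    rng = np.random.default_rng(seed)
    ids, p, fam_of = _family_probabilities(spec, rng)
    if depth is None:
        depth = int(rng.integers(20000, 60001))
    counts = rng.multinomial(depth, p)
    table = CountTable(pd.DataFrame([counts], index=[spec.name], columns=ids))
    phylum_of = {f.name: f.phylum for f in spec.families}
    return table, _taxonomy_for(fam_of, phylum_of)


# ---------------------------------------------------------------------------
# ASV id sharing across communities

#: fraction of a later community's family richness reused from earlier pools
_SHAM_SHARE = 0.45
_RECIPIENT_SHARE = 0.12


def _allocate_ids(
    specs: Sequence[CommunitySpec], shares: Sequence[float]
) -> dict[str, list[str]]:
    """Deterministic per-community ASV id pools with controlled overlap.

    Each family keeps a growing global pool ``<family>_0000, ...``; a later
    community reuses the first ``round(share * n)`` pooled ids of the family
    (overlap with earlier communities) and mints the rest fresh.
    """
    pool: dict[str, int] = {}
    out: dict[str, list[str]] = {}
    for spec, share in zip(specs, shares):
        ids: list[str] = []
        for fam in spec.families:
            have = pool.get(fam.name, 0)
            reuse = min(have, int(round(share * fam.n_asvs)))
            fresh = fam.n_asvs - reuse
            ids.extend(f"{fam.name}_{k:04d}" for k in range(reuse))
            ids.extend(f"{fam.name}_{k:04d}" for k in range(have, have + fresh))
            pool[fam.name] = have + fresh
        out[spec.name] = ids
    return out


def _community_probs_for_ids(
    spec: CommunitySpec, ids: Sequence[str], rng: np.random.Generator
) -> pd.Series:
    targets = spec.effective_proportions()
    fam_groups: dict[str, list[str]] = {}
    for asv in ids:
        fam = asv.rsplit("_", 1)[0]
        fam_groups.setdefault(fam, []).append(asv)
    parts = {}
    for fam in spec.families:
        members = fam_groups[fam.name]
        alpha = np.full(len(members), spec.concentration / len(members))
        within = rng.dirichlet(alpha) if len(members) > 1 else np.ones(1)
        for asv, w in zip(members, within):
            parts[asv] = w * targets[fam.name]
    s = pd.Series(parts).loc[list(ids)]
    return s / s.sum()


# ---------------------------------------------------------------------------
# default ground truth

# cumulative arrival pattern of newly engrafting ASVs over the post-FMT days,
# echoing the study's rising transfer counts from D1 to D16
_ARRIVAL_WEIGHTS = {"D1": 0.20, "D3": 0.11, "D6": 0.27, "D9": 0.07, "D16": 0.35}


def default_truth(
    donor_present: Sequence[str],
    baseline_pool: Sequence[str],
    taxonomy: Taxonomy,
    rng: np.random.Generator,
    engraft_fraction: float = 0.35,
    carriage: float = 0.9,
    scale_range: tuple[float, float] = (0.001, 0.004),
    washout_family: str | None = "Enterobacteriaceae",
    n_washout: int = 4,
) -> EngraftmentTruth:
    """Truth table for one pair: a staggered engrafting subset plus an
    optional transiently-colonising (washed-out) family.

    Engrafting ASVs are picked among donor ASVs absent from the recipient
    baseline pool, so their ground-truth origin label is donor-only.  The
    washout family's chosen ASVs colonise at D1 and vanish from D6 onward.
    """
    donor_present = list(donor_present)
    eligible = [a for a in donor_present if a not in set(baseline_pool)]
    families = taxonomy.rank_labels(donor_present, "family")
    rows = {
        a: {"engrafts": False, "first_day": np.nan, "washout_day": np.nan,
            "carriage": np.nan, "abundance_scale": np.nan}
        for a in donor_present
    }
    washout_members: list[str] = []
    if washout_family is not None:
        fam_elig = [a for a in eligible if families[a] == washout_family]
        washout_members = list(rng.permutation(fam_elig)[:n_washout])
        for a in washout_members:
            rows[a] = {
                "engrafts": True, "first_day": "D1", "washout_day": "D6",
                "carriage": carriage,
                "abundance_scale": rng.uniform(*scale_range),
            }
    persistent_pool = [
        a for a in eligible
        if a not in set(washout_members) and families[a] != washout_family
    ]
    n_engraft = int(round(engraft_fraction * len(persistent_pool)))
    chosen = rng.permutation(persistent_pool)[:n_engraft]
    days = list(_ARRIVAL_WEIGHTS)
    weights = np.array(list(_ARRIVAL_WEIGHTS.values()))
    for a in chosen:
        rows[a] = {
            "engrafts": True,
            "first_day": days[rng.choice(len(days), p=weights / weights.sum())],
            "washout_day": np.nan,
            "carriage": carriage,
            "abundance_scale": rng.uniform(*scale_range),
        }
    return EngraftmentTruth(pd.DataFrame.from_dict(rows, orient="index"))


# ---------------------------------------------------------------------------
# full experiment


def generate_experiment(
    design: ExperimentDesign = ExperimentDesign(),
    seed: int = 0,
    rygb_spec: CommunitySpec | None = None,
    sham_spec: CommunitySpec | None = None,
    baseline_spec: CommunitySpec | None = None,
    truth: Mapping[str, EngraftmentTruth] | None = None,
    truth_kwargs: Mapping[str, object] | None = None,
) -> FmtExperiment:
    """Generate a complete two-group FMT experiment.

    Returns counts for the two pooled donor samples plus every recipient at
    every timepoint, the sample metadata, a merged taxonomy, the per-group
    ground truth, and a family-coherent random tree.  Fully deterministic
    given ``seed`` (independent substreams per sample).
    """
    rygb_spec = rygb_spec or rygb_donor_spec()
    sham_spec = sham_spec or sham_donor_spec()
    baseline_spec = baseline_spec or recipient_baseline_spec()
    root = np.random.SeedSequence(seed)
    (ss_pools, ss_donors, ss_truth, ss_recipients, ss_tree, ss_depths) = root.spawn(6)

    pools = _allocate_ids(
        [rygb_spec, sham_spec, baseline_spec], [0.0, _SHAM_SHARE, _RECIPIENT_SHARE]
    )
    rng_pool = np.random.default_rng(ss_pools)
    donor_probs = {
        "RYGB": _community_probs_for_ids(rygb_spec, pools[rygb_spec.name], rng_pool),
        "SHAM": _community_probs_for_ids(sham_spec, pools[sham_spec.name], rng_pool),
    }
    baseline_pool_probs = _community_probs_for_ids(
        baseline_spec, pools[baseline_spec.name], rng_pool
    )

    # merged taxonomy over the whole universe
    phylum_of: dict[str, str] = {}
    for spec in (rygb_spec, sham_spec, baseline_spec):
        phylum_of.update({f.name: f.phylum for f in spec.families})
    universe = sorted(set().union(*pools.values()))
    fam_of = {a: a.rsplit("_", 1)[0] for a in universe}
    taxonomy = _taxonomy_for(fam_of, phylum_of)

    rng_depth = np.random.default_rng(ss_depths)

    def draw_depth() -> int:
        return int(rng_depth.integers(design.depth_range[0], design.depth_range[1] + 1))

    samples: dict[str, pd.Series] = {}
    meta_rows: dict[str, dict[str, str]] = {}

    # pooled donor samples
    rng_donor = np.random.default_rng(ss_donors)
    for group, donor_id in (("RYGB", "RYGB_donor"), ("SHAM", "SHAM_donor")):
        p = donor_probs[group]
        counts = rng_donor.multinomial(draw_depth(), p.to_numpy())
        samples[donor_id] = pd.Series(counts, index=p.index)
        meta_rows[donor_id] = {
            "subject_id": donor_id, "role": "donor", "group": group, "timepoint": "donor",
        }

    # ground truth per group, conditioned on what the donor sample contains
    rng_truth = np.random.default_rng(ss_truth)
    baseline_ids = list(baseline_pool_probs.index)
    truth_kwargs = dict(truth_kwargs or {})
    if truth is None:
        truth = {}
        for group, donor_id in (("RYGB", "RYGB_donor"), ("SHAM", "SHAM_donor")):
            observed = samples[donor_id]
            donor_present = list(observed.index[observed > 0])
            kwargs = dict(truth_kwargs)
            if group == "SHAM":
                kwargs.setdefault("engraft_fraction", 0.12)
                kwargs.setdefault("washout_family", None)
            truth[group] = default_truth(
                donor_present, baseline_ids, taxonomy, rng_truth, **kwargs
            )

    # recipients
    subjects = [("RYGB", f"R{i + 1}") for i in range(design.n_rygbr)] + [
        ("SHAM", f"S{i + 1}") for i in range(design.n_shamr)
    ]
    bloom = dict(design.bloom_families)
    base_p = baseline_pool_probs.to_numpy()
    fam_arr = np.array([fam_of[a] for a in baseline_ids])
    bloom_mult = np.array([bloom.get(f, 1.0) for f in fam_arr])
    for (group, subject), ss_subj in zip(subjects, ss_recipients.spawn(len(subjects))):
        rng = np.random.default_rng(ss_subj)
        jitter = rng.dirichlet(design.recipient_jitter * base_p + 1e-12)
        p_baseline = jitter / jitter.sum()
        survival = rng.random(len(baseline_ids)) < design.antibiotic_survival
        tr = truth[group]
        tdata = tr.data
        engraft_ids = sorted(tr.engrafting)
        carrier = {a: rng.random() < tdata.at[a, "carriage"] for a in engraft_ids}
        for tp in design.timepoints:
            day = _day_number(tp)
            if day < 0:  # baseline
                w = pd.Series(p_baseline, index=baseline_ids)
            else:
                surv_w = p_baseline * survival * bloom_mult
                if surv_w.sum() == 0:
                    surv_w = p_baseline * bloom_mult
                indig = pd.Series(surv_w / surv_w.sum(), index=baseline_ids)
                if day == 0:  # post-antibiotics, pre-FMT
                    w = indig
                else:
                    active = {
                        a: tdata.at[a, "abundance_scale"]
                        for a in engraft_ids
                        if carrier[a] and tr.active(a, tp)
                    }
                    engraft_mass = sum(active.values())
                    w = indig * max(0.0, 1.0 - engraft_mass)
                    if active:
                        w = w.add(pd.Series(active), fill_value=0.0)
                    w = w / w.sum()
            sample_id = f"{subject}_{tp}"
            counts = rng.multinomial(draw_depth(), w.to_numpy())
            samples[sample_id] = pd.Series(counts, index=w.index)
            meta_rows[sample_id] = {
                "subject_id": subject, "role": "recipient", "group": group, "timepoint": tp,
            }

    counts_df = pd.DataFrame(0, index=list(samples), columns=universe, dtype=np.int64)
    for sid, vec in samples.items():
        counts_df.loc[sid, vec.index] = vec.to_numpy()
    table = CountTable(counts_df)
    meta = SampleMeta(pd.DataFrame.from_dict(meta_rows, orient="index"))
    tree = generate_tree(universe, seed=ss_tree, families=fam_of)
    return FmtExperiment(table, meta, taxonomy, truth, tree, design)


def generate_tree(
    asv_ids: Sequence[str],
    seed: int | np.random.SeedSequence,
    families: Mapping[str, str] | None = None,
) -> TreeNode:
    """Random rooted bifurcating tree over the ASVs with exponential branch
    lengths; members of a family coalesce together first so family structure
    is phylogenetically coherent."""
    ids = list(asv_ids)
    if len(ids) < 2:
        raise ValueError("need at least 2 ASVs")
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate ASV ids")
    rng = np.random.default_rng(seed)
    families = families or {a: a.rsplit("_", 1)[0] for a in ids}

    def join_all(nodes: list[TreeNode], scale: float) -> TreeNode:
        nodes = list(nodes)
        while len(nodes) > 1:
            i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
            b = nodes.pop(j)
            a = nodes.pop(i)
            parent = TreeNode(children=[a, b])
            parent.length = float(rng.exponential(scale))
            nodes.append(parent)
        return nodes[0]

    fam_groups: dict[str, list[str]] = {}
    for a in ids:
        fam_groups.setdefault(families.get(a, "_orphan"), []).append(a)
    subtrees = []
    for fam in sorted(fam_groups):
        tips = [TreeNode(name=a, length=float(rng.exponential(0.1))) for a in sorted(fam_groups[fam])]
        subtrees.append(join_all(tips, scale=0.1))
    root = join_all(subtrees, scale=0.3) if len(subtrees) > 1 else subtrees[0]
    root.length = None
    return root
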