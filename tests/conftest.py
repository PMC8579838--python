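"""Shared fixtures: small hand-sized tables and a reduced synthetic experiment."""

import numpy as np
import pandas as pd
import pytest

from fmtrack import (
    CommunitySpec,
    FamilySpec,
    CountTable,
    SampleMeta,
    Taxonomy,
    generate_experiment,
)


@pytest.fixture
def toy_table() -> CountTable:
    """3 samples x 4 ASVs with easily hand-checked sums."""
    return CountTable(
        pd.DataFrame(
            [[5, 0, 3, 2], [0, 7, 1, 0], [4, 4, 4, 4]],
            index=["s1", "s2", "s3"],
            columns=["a1", "a2", "a3", "a4"],
        )
    )


@pytest.fixture
def toy_taxonomy() -> Taxonomy:
    lineages = {
        "a1": "Bacteria;Firmicutes;Clostridia;Clostridiales;Lachnospiraceae;Blautia;",
        "a2": "Bacteria;Firmicutes;Clostridia;Clostridiales;Lachnospiraceae;Roseburia;",
        "a3": "Bacteria;Bacteroidetes;Bacteroidia;Bacteroidales;Muribaculaceae;;",
        "a4": "Bacteria;Bacteroidetes;Bacteroidia;Bacteroidales;;;",
    }
    return Taxonomy.from_lineages(lineages)


def small_specs() -> tuple[CommunitySpec, CommunitySpec, CommunitySpec]:
    """Scaled-down three-community design for fast plumbing tests."""
    rygb = CommunitySpec(
        "RYGB_donor",
        (
            FamilySpec("Enterobacteriaceae", "Proteobacteria", 5, 0.20),
            FamilySpec("Lachnospiraceae", "Firmicutes", 15, 0.50),
            FamilySpec("Muribaculaceae", "Bacteroidetes", 10, 0.30),
        ),
    )
    sham = CommunitySpec(
        "SHAM_donor",
        (
            FamilySpec("Enterobacteriaceae", "Proteobacteria", 2, 0.02),
            FamilySpec("Lachnospiraceae", "Firmicutes", 18, 0.58),
            FamilySpec("Muribaculaceae", "Bacteroidetes", 10, 0.40),
        ),
    )
    base = CommunitySpec(
        "recipient_baseline",
        (
            FamilySpec("Enterobacteriaceae", "Proteobacteria", 1, 0.01),
            FamilySpec("Lachnospiraceae", "Firmicutes", 12, 0.60),
            FamilySpec("Muribaculaceae", "Bacteroidetes", 8, 0.39),
        ),
    )
    return rygb, sham, base


@pytest.fixture(scope="session")
def small_experiment():
    rygb, sham, base = small_specs()
    return generate_experiment(
        seed=11,
        rygb_spec=rygb,
        sham_spec=sham,
        baseline_spec=base,
        truth_kwargs={"n_washout": 2},
    )


def meta_frame(rows: dict[str, tuple[str, str, str, str]]) -> SampleMeta:
    """rows: sample_id -> (subject, role, group, timepoint)."""
    df = pd.DataFrame.from_dict(
        rows, orient="index", columns=["subject_id", "role", "group", "timepoint"]
    )
    return SampleMeta(df)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
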