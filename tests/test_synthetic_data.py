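"""The mock-metatranscriptome generator: identity targeting, architecture
soundness, truth-table coverage and determinism."""

import numpy as np
import pytest

from prospector.io_formats import Contig
from prospector.orf_tools import detect_slippery_sites, find_orfs, translate
from prospector.synthetic_data import (
    GenerationError,
    LibraryPlan,
    VirusPlan,
    default_plan,
    generate_library,
    mutate_protein,
    percent_identity_ungapped,
    plan_from_yaml,
    plan_to_yaml,
    plant_viral_contig,
    random_protein,
    write_library,
)


def test_mutate_identity_100_is_identity(rng):
    protein = random_protein(rng, 120)
    assert mutate_protein(protein, 100, seed=5) == protein


def test_mutate_300aa_at_30_percent(rng):
    protein = random_protein(rng, 300)
    mutant = mutate_protein(protein, 30, seed=7)
    assert len(mutant) == len(protein)
    assert 28 <= percent_identity_ungapped(protein, mutant) <= 32


def test_mutate_20aa_at_50_percent(rng):
    protein = random_protein(rng, 20)
    mutant = mutate_protein(protein, 50, seed=1)
    matches = sum(a == b for a, b in zip(protein, mutant))
    assert abs(matches - 10) <= 1


def test_mutate_rejects_bad_targets(rng):
    protein = random_protein(rng, 50)
    with pytest.raises(ValueError):
        mutate_protein(protein, 0, seed=1)
    with pytest.raises(ValueError):
        mutate_protein(protein, 101, seed=1)
    with pytest.raises(ValueError):
        mutate_protein("MKLVW", 50, seed=1)  # too short


def test_identity_targeting_across_many_draws(rng):
    """Realized divergence stays within ±2 points of target."""
    protein = random_protein(rng, 333)
    for _ in range(100):
        target = float(rng.uniform(10, 100))
        mutant = mutate_protein(protein, target, seed=int(rng.integers(2**31)))
        assert abs(percent_identity_ungapped(protein, mutant) - target) <= 2.0


def test_mutation_is_deterministic_under_seed(rng):
    protein = random_protein(rng, 100)
    assert mutate_protein(protein, 40, seed=9) == mutate_protein(protein, 40, seed=9)


# ---------------------------------------------------------------------------
# Planting


def test_single_orf_plant_recovers_orf_at_recorded_coordinates():
    plan = VirusPlan(name="v", rdrp_source="rdrpA", target_identity=70)
    contig, row = plant_viral_contig(plan, seed=2)
    orfs = find_orfs(contig, code=1, min_aa=200)
    assert any(
        o.start == row["orf_start"] and o.end == row["orf_end"] and o.strand == "+"
        for o in orfs
    )
    planted = next(o for o in orfs if o.start == row["orf_start"])
    assert planted.aa_seq == row["protein"]


def test_frameshift_plant_contains_heptamer_at_recorded_overlap():
    plan = VirusPlan(
        name="v",
        rdrp_source="rdrpA",
        target_identity=80,
        genome_architecture="two_orf_frameshift",
    )
    contig, row = plant_viral_contig(plan, seed=4)
    assert contig.seq[row["slip_pos"] : row["slip_pos"] + 7] == "GGATTTT"
    assert detect_slippery_sites(contig) == [row["slip_pos"]]
    assert row["orf_start"] <= row["slip_pos"] < row["orf_end"]


def test_code4_virus_truncates_under_standard_translation():
    plan = VirusPlan(
        name="v", rdrp_source="rdrpA", target_identity=90, genetic_code=4
    )
    # Draw seeds until the mutant's coding sequence actually uses TGA=Trp.
    for seed in range(20):
        contig, row = plant_viral_contig(plan, seed=seed)
        coding = contig.seq[row["orf_start"] : row["orf_end"]]
        if "W" in row["protein"] and "*" in translate(coding, 1):
            break
    else:
        pytest.fail("no TGA-using mutant drawn")
    assert translate(coding, 4) == row["protein"]
    longest_code1 = max(
        (len(o) for o in find_orfs(Contig("c", coding), code=1, min_aa=1)), default=0
    )
    assert longest_code1 < len(row["protein"])


def test_architecture_length_conflict_raises():
    plan = VirusPlan(
        name="v", rdrp_source="rdrpA", target_identity=80, genome_length=300
    )
    with pytest.raises(GenerationError):
        plant_viral_contig(plan, seed=1)


def test_virus_plan_validation():
    with pytest.raises(ValueError):
        VirusPlan(name="v", rdrp_source="rdrpA", target_identity=0)
    with pytest.raises(ValueError):
        VirusPlan(name="v", rdrp_source="rdrpA", target_identity=50, genetic_code=11)
    with pytest.raises(ValueError):
        VirusPlan(
            name="v", rdrp_source="rdrpA", target_identity=50,
            genome_architecture="circular",
        )


# ---------------------------------------------------------------------------
# Whole libraries


def test_truth_table_covers_every_contig(library_bundle):
    ids = {c.id for c in library_bundle.contigs}
    assert set(library_bundle.truth["contig_id"]) == ids
    assert len(library_bundle.truth) == len(ids)
    classes = set(library_bundle.truth["class"])
    assert classes <= {"host", "rrna_like", "phage_decoy", "virus"}


def test_truth_coordinates_inside_contig_bounds(library_bundle):
    seqs = {c.id: c.seq for c in library_bundle.contigs}
    viruses = library_bundle.truth[library_bundle.truth["class"] == "virus"]
    for _, row in viruses.iterrows():
        assert 0 <= row["orf_start"] < row["orf_end"] <= len(seqs[row["contig_id"]])


def test_zero_virus_plan_yields_zero_virus_rows():
    plan = LibraryPlan(seed=3, n_host_contigs=5, n_rrna_like=1, n_decoy_phage=1)
    bundle = generate_library(plan)
    assert (bundle.truth["class"] == "virus").sum() == 0


def test_three_virus_identities_recorded():
    plan = LibraryPlan(
        seed=5,
        n_host_contigs=3,
        planted_viruses=[
            VirusPlan(name=f"v{t}", rdrp_source="rdrpA", target_identity=t)
            for t in (80, 40, 20)
        ],
    )
    bundle = generate_library(plan)
    viruses = bundle.truth[bundle.truth["class"] == "virus"]
    assert sorted(viruses["target_identity"]) == [20, 40, 80]
    for _, row in viruses.iterrows():
        assert abs(row["realized_identity"] - row["target_identity"]) <= 2.0


def test_generation_is_byte_deterministic(tmp_path):
    plan = default_plan(seed=11)
    p1 = write_library(generate_library(plan), tmp_path / "a")
    p2 = write_library(generate_library(default_plan(seed=11)), tmp_path / "b")
    assert p1["fasta"].read_bytes() == p2["fasta"].read_bytes()
    assert p1["counts"].read_bytes() == p2["counts"].read_bytes()
    assert p1["truth"].read_bytes() == p2["truth"].read_bytes()


def test_different_seeds_differ(tmp_path):
    a = write_library(generate_library(default_plan(seed=1)), tmp_path / "a")
    b = write_library(generate_library(default_plan(seed=2)), tmp_path / "b")
    assert a["fasta"].read_bytes() != b["fasta"].read_bytes()


def test_total_reads_invariant_enforced():
    with pytest.raises(ValueError):
        LibraryPlan(
            total_non_rrna_reads=100,
            planted_viruses=[
                VirusPlan(name="v", rdrp_source="rdrpA", target_identity=50, read_count=200)
            ],
        )


def test_plan_yaml_roundtrip(tmp_path):
    plan = default_plan(seed=7)
    path = tmp_path / "plan.yaml"
    plan_to_yaml(plan, path)
    back = plan_from_yaml(path)
    assert back == plan
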