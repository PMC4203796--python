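"""Generator: planted truth, count model, support files, determinism."""

import filecmp

import numpy as np
import pytest
from scipy import stats

from crossdev.io import CountDataset
from crossdev.orthology import read_hits, read_triads, triads_from_hits
from crossdev.stages import STAGE_NAMES
from crossdev.synthetic import (
    GenerationConfig,
    emit_support_files,
    generate_truth,
    simulate_counts,
)


def test_canonical_stage_grid_has_eight_stages():
    truth = generate_truth(GenerationConfig(n_genes=3), seed=0)
    assert truth.stage_names == STAGE_NAMES
    assert len(truth.stage_names) == 8
    assert truth.stage_names[0] == "BC" and truth.stage_names[-1] == "144h"


def test_zero_divergent_fraction_gives_identical_species():
    truth = generate_truth(GenerationConfig(n_genes=25, fraction_divergent=0.0), seed=3)
    assert truth.divergent == {}
    a, b, c = truth.species_ids
    np.testing.assert_array_equal(truth.levels[a].to_numpy(), truth.levels[b].to_numpy())
    np.testing.assert_array_equal(truth.levels[a].to_numpy(), truth.levels[c].to_numpy())


def test_planted_fold_change_is_exact(small_truth):
    truth = small_truth
    focal = truth.config.species_ids[0]
    others = [sp for sp in truth.species_ids if sp != focal]
    assert truth.divergent, "fixture should plant divergent genes"
    for g, div in truth.divergent.items():
        assert div.focal_species == focal
        assert div.fold >= 1.0
        for stage in truth.stage_names:
            lv_focal = truth.levels[focal].iloc[g][stage]
            lv_other = truth.levels[others[0]].iloc[g][stage]
            if stage in div.stages:
                assert lv_focal / lv_other == pytest.approx(div.fold, rel=1e-12)
            else:
                assert lv_focal == lv_other
        # the two non-focal species always share levels
        np.testing.assert_array_equal(
            truth.levels[others[0]].iloc[g].to_numpy(),
            truth.levels[others[1]].iloc[g].to_numpy(),
        )


@pytest.mark.parametrize(
    "kwargs",
    [
        {"n_genes": 0},
        {"fraction_divergent": 1.0},
        {"fraction_divergent": -0.1},
        {"fold_min": 0.5},
        {"fold_min": 4.0, "fold_max": 2.0},
        {"species_ids": ("a", "a", "b")},
    ],
)
def test_invalid_generation_parameters_raise(kwargs):
    with pytest.raises(ValueError):
        generate_truth(GenerationConfig(**kwargs), seed=0)


def test_generation_is_deterministic_and_seed_sensitive():
    config = GenerationConfig(n_genes=30, fraction_divergent=0.2)
    t1 = generate_truth(config, seed=11)
    t2 = generate_truth(config, seed=11)
    t3 = generate_truth(config, seed=12)
    for sp in config.species_ids:
        np.testing.assert_array_equal(t1.levels[sp].to_numpy(), t2.levels[sp].to_numpy())
        assert not np.array_equal(t1.levels[sp].to_numpy(), t3.levels[sp].to_numpy())
    assert t1.divergent == t2.divergent
    assert t1.category_map == t2.category_map


def test_emitted_files_are_byte_identical_across_reruns(tmp_path):
    config = GenerationConfig(n_genes=12, fraction_divergent=0.25)
    for run in ("a", "b"):
        truth = generate_truth(config, seed=5)
        emit_support_files(truth, tmp_path / run, seed=5)
    names = [p.name for p in (tmp_path / "a").iterdir()]
    match, mismatch, errors = filecmp.cmpfiles(
        tmp_path / "a", tmp_path / "b", names, shallow=False
    )
    assert not mismatch and not errors and len(match) == len(names)


def test_zero_true_level_yields_zero_counts():
    truth = generate_truth(GenerationConfig(n_genes=10), seed=2)
    sp = truth.species_ids[0]
    truth.levels[sp].iloc[0] = 0.0
    counts = simulate_counts(truth, depth=1e6, seed=2)
    assert (counts.counts[sp].iloc[0] == 0).all()


def test_counts_match_poisson_mean():
    """Empirical mean over 10,000 draws within 3 SE of depth * level."""
    truth = generate_truth(GenerationConfig(n_genes=10_000, fraction_divergent=0.0), seed=9)
    sp = truth.species_ids[0]
    truth.levels[sp].iloc[:, :] = 1e-5
    counts = simulate_counts(truth, depth=1e6, seed=9)
    draws = counts.counts[sp]["BC"].to_numpy()
    se = np.sqrt(10.0 / len(draws))
    assert abs(draws.mean() - 10.0) < 3 * se


def test_equal_depth_equal_level_gives_same_distribution():
    """KS two-sample test on 5,000 paired draws is not rejected."""
    truth = generate_truth(GenerationConfig(n_genes=5_000, fraction_divergent=0.0), seed=12345)
    sp = truth.species_ids[0]
    truth.levels[sp].iloc[:, :] = 5e-5
    counts = simulate_counts(truth, depth=1e6, seed=12345)
    stat = stats.ks_2samp(
        counts.counts[sp]["BC"].to_numpy(), counts.counts[sp]["2h"].to_numpy()
    )
    assert stat.pvalue > 0.01


def test_moment_recovery_relative_error_below_2pct():
    """Mean of counts/depth recovers true levels (mean count >= 50)."""
    truth = generate_truth(GenerationConfig(n_genes=10_000, fraction_divergent=0.0), seed=4)
    sp = truth.species_ids[0]
    truth.levels[sp].iloc[:, :] = 5e-5  # mean count 50 at depth 1e6
    counts = simulate_counts(truth, depth=1e6, seed=4)
    est = counts.counts[sp]["48h"].to_numpy().mean() / 1e6
    assert abs(est - 5e-5) / 5e-5 < 0.02


def test_realized_fold_change_within_25pct():
    """Counts at mean >= 100 reproduce the planted fold within 25%."""
    config = GenerationConfig(n_genes=400, fraction_divergent=0.25)
    truth = generate_truth(config, seed=21)
    depth = 2e7
    counts = simulate_counts(truth, depth=depth, seed=21)
    focal = truth.species_ids[0]
    other = truth.species_ids[1]
    checked = 0
    for g, div in truth.divergent.items():
        base = truth.levels[other].iloc[g][list(div.stages)].to_numpy()
        if (base * depth).min() < 100:
            continue
        pooled_focal = counts.counts[focal].iloc[g][list(div.stages)].sum()
        pooled_other = counts.counts[other].iloc[g][list(div.stages)].sum()
        realized = pooled_focal / pooled_other
        assert abs(realized - div.fold) / div.fold < 0.25
        checked += 1
    assert checked >= 30


def test_missing_depth_raises():
    truth = generate_truth(GenerationConfig(n_genes=4), seed=0)
    with pytest.raises(ValueError, match="missing depth"):
        simulate_counts(truth, depth={truth.species_ids[0]: {"BC": 1e6}}, seed=0)
    with pytest.raises(ValueError, match="non-positive"):
        simulate_counts(truth, depth=0.0, seed=0)


def test_support_file_shapes(tmp_path):
    truth = generate_truth(GenerationConfig(n_genes=5, fraction_divergent=0.0), seed=1)
    paths = emit_support_files(truth, tmp_path, seed=1)
    triads = read_triads(paths["triads"])
    assert len(triads) == 5
    assert all(len(t.genes) == 3 for t in triads)
    assert len([k for k in paths if k.startswith("hits_")]) == 6


def _recover(truth, paths, e_threshold=1e-4):
    a, b, c = truth.species_ids
    tables = [
        read_hits(paths[f"hits_{x}_{y}"])
        for x, y in ((a, b), (b, a), (a, c), (c, a), (b, c), (c, b))
    ]
    return triads_from_hits(*tables, e_threshold=e_threshold)


def test_rbh_recovers_triads_exactly_without_decoys(tmp_path):
    truth = generate_truth(GenerationConfig(n_genes=20), seed=6)
    paths = emit_support_files(truth, tmp_path, n_decoys=0,
                               p_superthreshold_decoy=0.0, seed=6)
    recovered = _recover(truth, paths)
    assert {t.genes for t in recovered} == {t.genes for t in truth.triads()}


def test_superthreshold_decoys_are_filtered_out(tmp_path):
    """A decoy with a higher bitscore but e-value 1e-3 never displaces a
    true ortholog pair at the default 1e-4 cutoff."""
    truth = generate_truth(GenerationConfig(n_genes=20), seed=8)
    paths = emit_support_files(truth, tmp_path, n_decoys=2,
                               p_superthreshold_decoy=1.0, seed=8)
    recovered = _recover(truth, paths)
    assert {t.genes for t in recovered} == {t.genes for t in truth.triads()}


def test_unwritable_outdir_raises(tmp_path):
    blocker = tmp_path / "blocker"
    blocker.write_text("not a directory")
    truth = generate_truth(GenerationConfig(n_genes=3), seed=0)
    with pytest.raises(OSError):
        emit_support_files(truth, blocker / "sub", seed=0)


def test_negative_binomial_option_inflates_variance():
    config_nb = GenerationConfig(n_genes=4_000, fraction_divergent=0.0, nb_dispersion=2.0)
    truth = generate_truth(config_nb, seed=13)
    sp = truth.species_ids[0]
    truth.levels[sp].iloc[:, :] = 1e-4
    nb_counts = simulate_counts(truth, depth=1e6, seed=13).counts[sp]["BC"]
    # Poisson(100) variance is 100; NB with shape 2 adds mu^2/shape = 5000
    assert nb_counts.var() > 1_000


def test_count_dataset_round_trip(tmp_path, small_dataset):
    from crossdev.io import read_counts, write_counts

    write_counts(small_dataset, tmp_path / "c.tsv", tmp_path / "l.tsv")
    back = read_counts(tmp_path / "c.tsv", tmp_path / "l.tsv")
    for sp in small_dataset.species:
        np.testing.assert_array_equal(
            back.counts[sp].to_numpy(), small_dataset.counts[sp].to_numpy()
        )
        np.testing.assert_array_equal(
            back.library_size[sp].to_numpy(), small_dataset.library_size[sp].to_numpy()
        )


def test_count_dataset_rejects_bad_input(small_dataset):
    import pandas as pd

    with pytest.raises(ValueError, match="negative"):
        CountDataset(
            {"x": pd.DataFrame({"BC": [-1], "2h": [2]}, index=["g"])},
            {"x": pd.Series({"BC": 10, "2h": 10})},
        )
    with pytest.raises(ValueError, match="library size"):
        CountDataset(
            {"x": pd.DataFrame({"BC": [1], "2h": [2]}, index=["g"])},
            {"x": pd.Series({"BC": 0, "2h": 10})},
        )
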