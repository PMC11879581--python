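"""C+T engine: clumping vs an exhaustive reference, scoring identities, I/O."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from suscept_gxe import prs_engine
from suscept_gxe.prs_engine import (GenotypePanel, PanelLD, TableLD, clump,
                                    construct_prs, score, threshold_select)


# ---------------------------------------------------------------------------
# reference implementations (independent oracles)
# ---------------------------------------------------------------------------

def reference_clump(gwas, r2_lookup, r2_threshold, window_kb):
    """Literal greedy-by-p clumping with explicit pairwise loops."""
    rows = sorted(gwas.to_dict("records"), key=lambda r: (r["P"], r["SNP"]))
    removed = set()
    kept = []
    for row in rows:
        if row["SNP"] in removed:
            continue
        kept.append(row["SNP"])
        for other in rows:
            s = other["SNP"]
            if s == row["SNP"] or s in removed or s in kept:
                continue
            if other["CHR"] != row["CHR"]:
                continue
            if abs(other["BP"] - row["BP"]) > window_kb * 1000:
                continue
            key = tuple(sorted((row["SNP"], s)))
            if r2_lookup.get(key, 0.0) >= r2_threshold:
                removed.add(s)
    return kept


def random_instance(rng, max_snps=20):
    m = rng.integers(1, max_snps + 1)
    snps = [f"v{j}" for j in range(m)]
    gwas = pd.DataFrame({
        "SNP": snps,
        "CHR": rng.choice(["1", "2"], size=m),
        "BP": rng.integers(1, 3_000_000, size=m),
        "A1": "A", "A2": "G",
        "BETA": rng.normal(size=m),
        "P": rng.uniform(1e-8, 1.0, size=m),
    })
    pairs = {}
    rows = []
    for i in range(m):
        for j in range(i + 1, m):
            r2 = float(rng.uniform(0, 1))
            pairs[tuple(sorted((snps[i], snps[j])))] = r2
            rows.append({"snp_a": snps[i], "snp_b": snps[j], "r2": r2})
    ld_df = pd.DataFrame(rows) if rows else pd.DataFrame(
        {"snp_a": snps, "snp_b": snps, "r2": 1.0})
    return gwas, pairs, ld_df


# ---------------------------------------------------------------------------
# clumping
# ---------------------------------------------------------------------------

def _gwas(snps, chrs, bps, ps):
    return pd.DataFrame({"SNP": snps, "CHR": chrs, "BP": bps,
                         "A1": "A", "A2": "G", "BETA": 0.1, "P": ps})


def test_clump_single_snp_retained():
    gwas = _gwas(["rs1"], ["1"], [100], [0.5])
    ld = TableLD(pd.DataFrame({"snp_a": ["rs1"], "snp_b": ["rs1"], "r2": [1.0]}))
    assert clump(gwas, ld) == ["rs1"]


def test_clump_three_snp_worked_example():
    # index SNP1 (p 1e-8) removes SNP2 (r2 .5 >= .1); SNP3 survives (r2 .05)
    gwas = _gwas(["rs1", "rs2", "rs3"], ["1"] * 3, [100, 200, 300],
                 [1e-8, 1e-4, 1e-3])
    ld = TableLD(pd.DataFrame({
        "snp_a": ["rs1", "rs1", "rs2"],
        "snp_b": ["rs2", "rs3", "rs3"],
        "r2": [0.5, 0.05, 0.04]}))
    assert set(clump(gwas, ld, r2_threshold=0.1)) == {"rs1", "rs3"}


def test_clump_window_excludes_distant_pairs():
    # r2 .9 but 2000 kb apart with a 1000 kb window: both retained
    gwas = _gwas(["rs1", "rs2"], ["1", "1"], [1, 2_000_001], [1e-4, 1e-3])
    ld = TableLD(pd.DataFrame({"snp_a": ["rs1"], "snp_b": ["rs2"], "r2": [0.9]}))
    assert set(clump(gwas, ld, window_kb=1000)) == {"rs1", "rs2"}


def test_clump_matches_exhaustive_reference_on_random_instances():
    rng = np.random.default_rng(42)
    for _ in range(200):
        gwas, pairs, ld_df = random_instance(rng)
        thr = float(rng.uniform(0.05, 0.95))
        win = float(rng.uniform(100, 2000))
        got = clump(gwas, TableLD(ld_df), r2_threshold=thr, window_kb=win)
        assert got == reference_clump(gwas, pairs, thr, win)


def test_clump_postconditions_on_random_instance():
    # every retained pair in a window has r2 < threshold
    rng = np.random.default_rng(7)
    gwas, pairs, ld_df = random_instance(rng, max_snps=15)
    thr = 0.3
    kept = clump(gwas, TableLD(ld_df), r2_threshold=thr, window_kb=500)
    pos = gwas.set_index("SNP")
    for i, a in enumerate(kept):
        for b in kept[i + 1:]:
            if pos.loc[a, "CHR"] != pos.loc[b, "CHR"]:
                continue
            if abs(pos.loc[a, "BP"] - pos.loc[b, "BP"]) > 500_000:
                continue
            assert pairs[tuple(sorted((a, b)))] < thr


def test_clump_missing_snp_policy():
    gwas = _gwas(["rs1", "rs2"], ["1", "1"], [100, 200], [0.01, 0.02])
    ld = TableLD(pd.DataFrame({"snp_a": ["rs1"], "snp_b": ["rs1"], "r2": [1.0]}))
    with pytest.warns(UserWarning, match="absent"):
        assert clump(gwas, ld) == ["rs1"]
    with pytest.raises(KeyError):
        clump(gwas, ld, missing="strict")


def test_clump_parameter_validation():
    gwas = _gwas(["rs1"], ["1"], [100], [0.5])
    ld = TableLD(pd.DataFrame({"snp_a": ["rs1"], "snp_b": ["rs1"], "r2": [1.0]}))
    with pytest.raises(ValueError):
        clump(gwas, ld, r2_threshold=0.0)
    with pytest.raises(ValueError):
        clump(gwas, ld, window_kb=-5)


# ---------------------------------------------------------------------------
# thresholding
# ---------------------------------------------------------------------------

def test_threshold_select_worked_example():
    gwas = _gwas(["a", "b", "c"], ["1"] * 3, [1, 2, 3], [0.0005, 0.02, 0.2])
    sets = threshold_select(gwas, ["a", "b", "c"], (0.001, 0.01, 0.05, 0.1))
    assert [len(sets[t]) for t in (0.001, 0.01, 0.05, 0.1)] == [1, 1, 2, 2]


def test_threshold_select_all_p_one_gives_empty_sets():
    gwas = _gwas(["a", "b"], ["1", "1"], [1, 2], [1.0, 1.0])
    sets = threshold_select(gwas, ["a", "b"], (0.05, 0.1))
    assert all(len(v) == 0 for v in sets.values())


@settings(max_examples=50, deadline=None, derandomize=True)
@given(ps=st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=30),
       data=st.data())
def test_threshold_select_nestedness(ps, data):
    snps = [f"s{i}" for i in range(len(ps))]
    gwas = _gwas(snps, ["1"] * len(ps), list(range(1, len(ps) + 1)), ps)
    thresholds = sorted(data.draw(st.lists(
        st.floats(1e-4, 1.0), min_size=2, max_size=5, unique=True)))
    sets = threshold_select(gwas, snps, thresholds)
    for t1, t2 in zip(thresholds, thresholds[1:]):
        assert set(sets[t1]) <= set(sets[t2])


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def _gwas_for(panel, betas, flip=None):
    flip = flip or [False] * panel.n_snps
    return pd.DataFrame({
        "SNP": panel.markers["snp"],
        "CHR": panel.markers["chr"], "BP": panel.markers["bp"],
        "A1": np.where(flip, panel.markers["a2"], panel.markers["a1"]),
        "A2": np.where(flip, panel.markers["a1"], panel.markers["a2"]),
        "BETA": betas, "P": 0.01,
    })


def test_score_hand_sum(toy_panel):
    gwas = _gwas_for(toy_panel, [0.5, -0.3])
    profile = score(toy_panel, gwas, ["rs1", "rs2"], standardize=False)
    np.testing.assert_allclose(profile.scores["score"], [1.0, 0.2, -0.6])


def test_score_allele_flip_identity(toy_panel):
    # GWAS reports the panel's other allele: dosage 2 becomes 0
    gwas = _gwas_for(toy_panel, [0.5, 0.0], flip=[True, False])
    profile = score(toy_panel, gwas, ["rs1"], standardize=False)
    np.testing.assert_allclose(profile.scores["score"], [0.0, 0.5, 1.0])


def test_score_linearity_in_betas():
    rng = np.random.default_rng(3)
    from suscept_gxe.synthetic_cohort import simulate_genotypes
    panel = simulate_genotypes(40, 12, seed=9)
    betas = rng.normal(size=12)
    gwas = _gwas_for(panel, betas)
    s1 = score(panel, gwas, list(panel.markers["snp"]), standardize=False)
    gwas2 = gwas.assign(BETA=2 * gwas["BETA"])
    s2 = score(panel, gwas2, list(panel.markers["snp"]), standardize=False)
    np.testing.assert_allclose(2 * s1.scores["score"], s2.scores["score"],
                               atol=1e-12)


def test_score_invariant_to_allele_swap_with_sign_flip():
    from suscept_gxe.synthetic_cohort import simulate_genotypes
    panel = simulate_genotypes(30, 8, seed=5)
    rng = np.random.default_rng(1)
    betas = rng.normal(size=8)
    flip = rng.random(8) < 0.5
    direct = score(panel, _gwas_for(panel, betas), list(panel.markers["snp"]),
                   standardize=False).scores["score"]
    swapped = score(panel,
                    _gwas_for(panel, np.where(flip, -betas, betas), flip=list(flip)),
                    list(panel.markers["snp"]), standardize=False).scores["score"]
    # swapping (effect, other) with beta -> -beta shifts by a constant
    # 2*sum(flipped betas); centered scores are identical
    np.testing.assert_allclose(direct - direct.mean(),
                               swapped - swapped.mean(), atol=1e-10)


def test_score_ambiguous_alleles_dropped():
    markers = pd.DataFrame({"snp": ["rs1"], "chr": ["1"], "bp": [100],
                            "a1": ["A"], "a2": ["T"]})
    panel = GenotypePanel(ids=np.array(["x"], dtype=object), markers=markers,
                          dosages=np.array([[2.0]]))
    gwas = pd.DataFrame({"SNP": ["rs1"], "CHR": ["1"], "BP": [100],
                         "A1": ["A"], "A2": ["T"], "BETA": [1.0], "P": [0.5]})
    with pytest.warns(UserWarning, match="dropped"):
        profile = score(panel, gwas, ["rs1"], standardize=False)
    assert profile.snp_counts["score"] == 0
    assert profile.scores["score"].iloc[0] == 0.0
    with pytest.raises(ValueError):
        score(panel, gwas, ["rs1"], allele_policy="strict")


def test_standardized_scores_invariant_to_affine_beta_transform():
    from suscept_gxe.synthetic_cohort import simulate_genotypes
    panel = simulate_genotypes(60, 10, seed=2)
    rng = np.random.default_rng(4)
    betas = rng.normal(size=10)
    snps = list(panel.markers["snp"])
    base = score(panel, _gwas_for(panel, betas), snps).scores["score"]
    scaled = score(panel, _gwas_for(panel, 3.7 * betas), snps).scores["score"]
    np.testing.assert_allclose(base, scaled, atol=1e-8)


def test_construct_prs_counts_monotone_in_threshold(default_cohort):
    counts = [default_cohort.meta["snp_counts"][k]
              for k in sorted(default_cohort.meta["snp_counts"], key=float)]
    assert counts == sorted(counts)


# ---------------------------------------------------------------------------
# containers and I/O
# ---------------------------------------------------------------------------

def test_panel_validation_rejects_bad_inputs(toy_panel):
    with pytest.raises(ValueError, match="dosages"):
        GenotypePanel(ids=toy_panel.ids, markers=toy_panel.markers,
                      dosages=toy_panel.dosages + 5)
    dup = toy_panel.markers.copy()
    dup.loc[1, "snp"] = "rs1"
    with pytest.raises(ValueError, match="duplicate"):
        GenotypePanel(ids=toy_panel.ids, markers=dup, dosages=toy_panel.dosages)


def test_raw_round_trip(tmp_path, toy_panel):
    path = tmp_path / "panel.raw"
    toy_panel.to_raw(str(path))
    header = path.read_text().splitlines()[0].split(" ")
    assert header[:6] == ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
    assert header[6:] == ["rs1_A", "rs2_G"]
    back = GenotypePanel.from_raw(str(path), markers=toy_panel.markers)
    np.testing.assert_allclose(back.dosages, toy_panel.dosages)
    assert list(back.markers["bp"]) == [1000, 2000]


def test_csv_round_trip(tmp_path, toy_panel):
    toy_panel.to_csv(str(tmp_path / "d.csv"), str(tmp_path / "m.csv"))
    back = GenotypePanel.from_csv(str(tmp_path / "d.csv"), str(tmp_path / "m.csv"))
    np.testing.assert_allclose(back.dosages, toy_panel.dosages)
    assert list(back.markers["snp"]) == ["rs1", "rs2"]


def test_gwas_validation():
    bad = pd.DataFrame({"SNP": ["a"], "CHR": ["1"], "BP": [1], "A1": ["A"],
                        "A2": ["G"], "BETA": [0.1], "P": [0.0]})
    with pytest.raises(ValueError, match="0, 1"):
        prs_engine.validate_gwas(bad)
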