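import numpy as np
import pandas as pd
import pytest
from scipy import sparse

import gcniche as gn
from gcniche import (
    ContaminationParams,
    ParameterError,
    TissueConfig,
    apply_contamination,
    default_gene_programs,
    expected_cell_count,
    generate_dissociated_reference,
    generate_gene_activity,
    generate_tissue,
    wilcoxon_contrast,
)
from gcniche.simulate import REGIONS

from conftest import make_cell_table


def test_generation_is_deterministic_for_fixed_seed():
    cfg = TissueConfig.small(seed=3)
    a = generate_tissue(cfg)
    b = generate_tissue(TissueConfig.small(seed=3))
    pd.testing.assert_frame_equal(a.cells.df, b.cells.df)
    assert (a.counts.X != b.counts.X).nnz == 0
    c = generate_tissue(TissueConfig.small(seed=4))
    assert len(c.cells) != len(a.cells) or (c.counts.X != a.counts.X).nnz > 0


def test_cell_count_matches_point_process_expectation():
    cfg = TissueConfig(seed=1)
    tissue = generate_tissue(cfg)
    expected = expected_cell_count(cfg)
    assert abs(len(tissue.cells) - expected) / expected < 0.10


def test_true_region_agrees_with_geometric_oracle(small_tissue):
    """Recompute every cell's region from coordinates and follicle geometry."""
    cfg = small_tissue.config
    truth = small_tissue.truth.cells
    fol = small_tissue.follicles
    for _, cell in truth.sample(400, random_state=0).iterrows():
        x, y = small_tissue.cells.df.set_index("cell_id").loc[cell.cell_id, ["x", "y"]]
        region = "Epithelium" if y < cfg.epithelium_band_um else "TZone"
        for f in fol[fol.sample_id == cell.sample_id].itertuples(index=False):
            d = np.hypot(x - f.cx, y - f.cy)
            if d <= f.radius:
                u = np.array([np.cos(f.split_angle), np.sin(f.split_angle)])
                side = (x - f.cx) * u[0] + (y - f.cy) * u[1]
                region = "GC_LZ" if side >= 0 else "GC_DZ"
            elif d <= f.radius + cfg.mantle_um:
                region = "Mantle"
        assert region == cell.true_region


def test_zero_contamination_restricted_gene_positives_all_in_gc():
    """With no contamination or ambient signal, a GC-Tfh gene is seen only there."""
    programs = default_gene_programs(class_counts={
        "gc_tfh_restricted": 1, "pan_tfh": 1, "gc_associated_unrestricted": 1,
        "gcb_restricted": 1, "fdc_restricted": 1, "non_gc_tfh": 1, "housekeeping": 1,
    })
    cfg = TissueConfig.small(
        seed=5, n_follicles=1, ambient_rate=0.0,
        contamination=ContaminationParams.none(), programs=programs,
    )
    tissue = generate_tissue(cfg)
    gene = programs.loc[programs.gene_class == "gc_tfh_restricted", "gene"].iloc[0]
    gi = list(tissue.counts.genes).index(gene)
    pos = np.asarray((tissue.counts.X[gi] >= 1).todense()).ravel()
    tfh = tissue.cells.type_l1 == "Tfh"
    in_gc = tissue.truth.cells.true_region.isin(["GC_LZ", "GC_DZ"]).to_numpy()
    assert pos.sum() > 0
    assert (pos <= (tfh & in_gc)).all()  # every positive cell is a GC Tfh


def test_contamination_identity_when_all_channels_off(clean_small_tissue):
    out, log = apply_contamination(
        clean_small_tissue.counts, clean_small_tissue.cells,
        ContaminationParams.none(), seed=9,
    )
    assert (out.X != clean_small_tissue.counts.X).nnz == 0
    assert log["n_diffused"] == 0 and log["n_swap_pairs"] == 0


def test_isolated_cell_retains_counts_under_full_diffusion():
    cells = make_cell_table([[0, 0]], ["Tfh"])
    counts = gn.CountMatrix.from_parts(["g"], ["c0"], sparse.csr_matrix([[7]]))
    out, _ = apply_contamination(
        cells=cells, counts=counts,
        params=ContaminationParams(diffusion_lambda=1.0, diffusion_radius_um=10,
                                   swap_prob=0, overlap_prob=0),
        seed=0,
    )
    assert out.X[0, 0] == 7


def test_diffusion_radius_must_be_positive():
    with pytest.raises(ParameterError, match="radius"):
        ContaminationParams(diffusion_lambda=0.5, diffusion_radius_um=0).validate()


def test_diffusion_conserves_totals_and_retains_expected_fraction():
    """3-cell line: per-gene sums conserved; donor keeps Binomial mean 1−λ."""
    cells = make_cell_table([[0, 0], [10, 0], [20, 0]], ["Tfh"] * 3)
    X = sparse.csr_matrix(np.array([[100, 0, 0], [0, 50, 0]]))
    counts = gn.CountMatrix.from_parts(["g1", "g2"], cells.cell_ids, X)
    params = ContaminationParams(diffusion_lambda=0.2, diffusion_radius_um=15,
                                 swap_prob=0, overlap_prob=0)
    retained = []
    for rep in range(1000):
        out, _ = apply_contamination(counts, cells, params, seed=rep)
        np.testing.assert_array_equal(
            np.asarray(out.X.sum(axis=1)).ravel(), [100, 50]
        )
        retained.append(out.X[0, 0])
    assert abs(np.mean(retained) - 80.0) < 1.0  # MC error at n=1000 ~ 0.13


def test_diffusion_and_swap_conserve_per_gene_totals_on_tissue():
    cfg = TissueConfig.small(
        seed=11,
        contamination=ContaminationParams(diffusion_lambda=0.15, swap_prob=0.05,
                                          overlap_prob=0.0),
    )
    tissue = generate_tissue(cfg)
    clean_totals = np.asarray(tissue.clean_counts.X.sum(axis=1)).ravel()
    observed_totals = np.asarray(tissue.counts.X.sum(axis=1)).ravel()
    np.testing.assert_array_equal(observed_totals, clean_totals)


def test_overlap_additions_are_logged_exactly(small_tissue):
    clean_totals = np.asarray(small_tissue.clean_counts.X.sum(axis=1)).ravel()
    observed_totals = np.asarray(small_tissue.counts.X.sum(axis=1)).ravel()
    np.testing.assert_array_equal(
        observed_totals, clean_totals + small_tissue.contamination_log["overlap_added_per_gene"]
    )


def test_planted_fourfold_effect_is_bonferroni_significant():
    """A >=4-fold regional modifier is detectable at n >= 500 cells/group."""
    for seed in (1, 2, 3):
        tissue = generate_tissue(TissueConfig(seed=seed))
        tfh = tissue.cells.type_l1 == "Tfh"
        in_gc = tissue.truth.cells.true_region.isin(["GC_LZ", "GC_DZ"]).to_numpy()
        assert (tfh & in_gc).sum() >= 500 and (tfh & ~in_gc).sum() >= 500
        res = wilcoxon_contrast(
            tissue.counts.X, tissue.counts.genes, tfh & in_gc, tfh & ~in_gc
        )
        merged = res.table.merge(tissue.truth.genes, on="gene")
        # gc-associated genes carry a 10-fold in-GC modifier among Tfh
        target = merged[merged.gene_class == "gc_associated_unrestricted"]
        assert (target.p_adj < 0.05).all() and (target.log2fc > 0).all()


def test_reference_recovers_planted_lineage_contrasts():
    ref = generate_dissociated_reference(seed=2, n_cells=2000)
    labels = ref.labels.labels.values
    tfh = labels == "Tfh"
    # raw means: planted lineage effects should appear, identical means should not
    res = wilcoxon_contrast(ref.counts.X, ref.counts.genes, tfh, ~tfh, normalize=False)
    merged = res.table.merge(default_gene_programs()[["gene", "gene_class"]], on="gene")
    tfh_genes = merged[merged.gene_class.isin(["gc_tfh_restricted", "pan_tfh"])]
    assert (tfh_genes.log2fc > 0).all()
    hk = merged[merged.gene_class == "housekeeping"]
    # identical planted means: no systematic lineage signal, only sampling noise
    assert abs(hk.log2fc.mean()) < 0.05
    big = generate_dissociated_reference(seed=2, n_cells=20000)
    res_big = wilcoxon_contrast(
        big.counts.X, big.counts.genes,
        big.labels.labels.values == "Tfh", big.labels.labels.values != "Tfh",
        normalize=False,
    )
    hk_big = res_big.table.merge(
        default_gene_programs()[["gene", "gene_class"]], on="gene"
    ).query("gene_class == 'housekeeping'")
    assert hk_big.log2fc.abs().mean() < 0.1


def test_reference_requires_two_lineages():
    with pytest.raises(ParameterError, match="lineages"):
        generate_dissociated_reference(composition={"Tfh": 1.0}, seed=0)


def test_reference_is_deterministic():
    a = generate_dissociated_reference(seed=5)
    b = generate_dissociated_reference(seed=5)
    assert (a.counts.X != b.counts.X).nnz == 0


def test_gene_activity_noise_behavior():
    ref = generate_dissociated_reference(seed=3, n_cells=300)
    clean = generate_gene_activity(ref, noise_sd=0.0, seed=0)
    # noiseless activity is a strictly monotone transform of the planted means
    order = np.argsort(ref.means, axis=None)
    assert np.all(np.diff(clean.ravel()[order]) >= 0)
    from scipy.stats import spearmanr

    rhos = []
    for sd in (0.1, 2.0, 50.0):
        act = generate_gene_activity(ref, noise_sd=sd, seed=1)
        rhos.append(spearmanr(act.ravel(), ref.means.ravel()).statistic)
    assert rhos[0] > rhos[1] > rhos[2]
    assert abs(rhos[2]) < 0.1
    with pytest.raises(ParameterError):
        generate_gene_activity(ref, noise_sd=-1, seed=0)


def test_composition_must_sum_to_one():
    comp = {r: dict(v) for r, v in gn.simulate.DEFAULT_COMPOSITION.items()}
    comp["TZone"]["Tfh"] += 0.1
    with pytest.raises(ParameterError, match="sums"):
        TissueConfig(composition=comp).validate()
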