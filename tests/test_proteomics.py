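import numpy as np
import pandas as pd
import pytest

from laccscreen.proteomics import (
    IntensityMatrix,
    ProteomicsParams,
    cv_profile,
    differential_abundance,
    impute_minprob,
    median_normalize,
    pca_samples,
    recurrence_filter,
    replicate_qc,
)


def matrix_from(values: np.ndarray, strains: list[str], types: list[str] | None = None):
    n_prot, n_samp = values.shape
    samples = [f"smp{i}" for i in range(n_samp)]
    meta = pd.DataFrame(
        {
            "strain_id": strains,
            "replicate_id": [f"r{i}" for i in range(n_samp)],
            "replicate_type": types or ["biological"] * n_samp,
        },
        index=pd.Index(samples, name="sample_id"),
    )
    df = pd.DataFrame(values, index=[f"P{i:03d}" for i in range(n_prot)], columns=samples)
    return IntensityMatrix(df, meta)


def lognormal_matrix(rng, n_prot, strains, types=None, missing_frac=0.0):
    vals = rng.lognormal(mean=10, sigma=1.0, size=(n_prot, len(strains)))
    if missing_frac:
        vals[rng.random(vals.shape) < missing_frac] = np.nan
    return matrix_from(vals, strains, types)


# -- container validation -------------------------------------------------------


def test_intensity_matrix_validation():
    with pytest.raises(ValueError, match="positive"):
        matrix_from(np.array([[1.0, -2.0]]), ["A", "A"])
    vals = np.array([[1.0, 2.0]])
    meta_mismatch = pd.DataFrame(
        {"strain_id": ["A"], "replicate_id": ["r0"], "replicate_type": ["biological"]},
        index=pd.Index(["only_one"], name="sample_id"),
    )
    with pytest.raises(ValueError, match="must match"):
        IntensityMatrix(pd.DataFrame(vals, columns=["a", "b"]), meta_mismatch)
    with pytest.raises(ValueError, match="replicate types"):
        matrix_from(vals, ["A", "A"], types=["biological", "weird"])


# -- replicate QC ----------------------------------------------------------------


def test_replicate_qc_keeps_concordant_drops_outlier(rng):
    base = rng.lognormal(10, 1, size=500)
    noise = lambda: np.exp(rng.normal(0, 0.05, 500))  # noqa: E731
    garbage = rng.lognormal(10, 1, size=500)  # unrelated draw
    vals = np.column_stack([base * noise(), base * noise(), garbage])
    m = matrix_from(vals, ["A", "A", "A"])
    filtered, report = replicate_qc(m, ProteomicsParams())
    assert list(filtered.intensity.columns) == ["smp0", "smp1"]
    rep = report.set_index("sample_id")
    assert bool(rep.loc["smp2", "excluded"])
    assert rep.loc["smp0", "best_r2"] > 0.85


def test_replicate_qc_two_replicate_tie_keeps_strain_nonempty(rng):
    base = rng.lognormal(10, 1, size=400)
    noise = lambda: np.exp(rng.normal(0, 0.05, 400))  # noqa: E731
    # strain B has two mutually discordant replicates; one of them tracks the
    # well-behaved strain-A profile and must be the one retained
    vals = np.column_stack(
        [base * noise(), base * noise(), base * noise(), rng.lognormal(10, 1, 400)]
    )
    m = matrix_from(vals, ["A", "A", "B", "B"])
    filtered, report = replicate_qc(m, ProteomicsParams())
    kept_b = [s for s in filtered.intensity.columns if filtered.metadata.loc[s, "strain_id"] == "B"]
    assert kept_b == ["smp2"]
    assert report.set_index("sample_id").loc["smp3", "excluded"]


def test_replicate_qc_single_sample_warns_but_keeps(rng):
    m = lognormal_matrix(rng, 50, ["A"])
    with pytest.warns(UserWarning, match="single sample"):
        filtered, _ = replicate_qc(m)
    assert filtered.intensity.shape == m.intensity.shape


# -- normalization ----------------------------------------------------------------


def test_median_normalize_equalizes_medians(rng):
    m = lognormal_matrix(rng, 301, ["A", "A", "B", "B"], missing_frac=0.1)
    out = median_normalize(m)
    medians = out.intensity.median(axis=0, skipna=True)
    target = float(m.intensity.median(axis=0, skipna=True).mean())
    assert np.allclose(medians, target, rtol=1e-12)
    # missing cells untouched
    assert out.intensity.isna().equals(m.intensity.isna())


def test_median_normalize_idempotent(rng):
    m = lognormal_matrix(rng, 200, ["A", "A", "B"])
    once = median_normalize(m)
    twice = median_normalize(once)
    assert np.allclose(once.intensity, twice.intensity, rtol=1e-12)


def test_median_normalize_rejects_all_missing_sample():
    vals = np.array([[1.0, np.nan], [2.0, np.nan]])
    with pytest.raises(ValueError, match="no observed"):
        median_normalize(matrix_from(vals, ["A", "A"]))


# -- imputation -------------------------------------------------------------------


def test_impute_minprob_completes_positive_reproducible(rng):
    m = lognormal_matrix(rng, 400, ["A", "A", "B", "B"], missing_frac=0.15)
    params = ProteomicsParams(seed=42)
    out1 = impute_minprob(m, params)
    out2 = impute_minprob(m, params)
    assert out1.n_missing == 0
    assert (out1.intensity.to_numpy() > 0).all()
    assert np.array_equal(out1.intensity.to_numpy(), out2.intensity.to_numpy())
    # observed cells unchanged
    obs = m.intensity.notna()
    assert np.array_equal(
        out1.intensity.to_numpy()[obs.to_numpy()], m.intensity.to_numpy()[obs.to_numpy()]
    )
    # a different seed gives different draws
    out3 = impute_minprob(m, ProteomicsParams(seed=43))
    assert not np.array_equal(out1.intensity.to_numpy(), out3.intensity.to_numpy())


def test_impute_minprob_draws_low(rng):
    m = lognormal_matrix(rng, 1000, ["A", "A"], missing_frac=0.1)
    out = impute_minprob(m, ProteomicsParams(seed=0))
    for s in m.intensity.columns:
        obs = m.intensity[s].dropna()
        imputed = out.intensity.loc[m.intensity[s].isna(), s]
        assert imputed.median() < obs.median()


def test_impute_minprob_sparse_sample_uses_global_quantile(rng):
    vals = rng.lognormal(10, 1, size=(30, 2))
    vals[5:, 1] = np.nan  # only 5 observed values in sample 2
    m = matrix_from(vals, ["A", "A"])
    with pytest.warns(UserWarning, match="global quantile"):
        out = impute_minprob(m, ProteomicsParams(seed=1))
    assert out.n_missing == 0


# -- differential abundance ---------------------------------------------------------


def planted_matrix(rng, log2_fc=2.0, n_prot=300, n_changed=20):
    base = rng.lognormal(12, 1, size=n_prot)
    cols, strains = [], []
    for strain, fc_mask in (("REF", 0.0), ("MUT", 1.0)):
        effect = np.ones(n_prot)
        effect[:n_changed] = 2.0 ** (log2_fc * fc_mask)
        for _ in range(4):
            cols.append(base * effect * np.exp(rng.normal(0, 0.1, n_prot)))
            strains.append(strain)
    return matrix_from(np.column_stack(cols), strains)


def test_differential_abundance_finds_planted_and_is_antisymmetric(rng):
    m = planted_matrix(rng)
    res = differential_abundance(m, "MUT", "REF")
    planted = res.iloc[:20]
    assert (planted["direction"] == "up").mean() > 0.9
    assert (res.iloc[20:]["direction"] == "ns").mean() > 0.95
    swapped = differential_abundance(m, "REF", "MUT")
    assert np.allclose(res["log2_fc"], -swapped["log2_fc"], rtol=1e-12)
    assert np.allclose(res["p_value"], swapped["p_value"], rtol=1e-9)


def test_differential_abundance_requires_complete_matrix(rng):
    m = lognormal_matrix(rng, 50, ["A", "A", "B", "B"], missing_frac=0.1)
    with pytest.raises(ValueError, match="missing cells"):
        differential_abundance(m, "A", "B")
    complete = lognormal_matrix(rng, 50, ["A", "B", "B"])
    with pytest.raises(ValueError, match="at least 2 replicates"):
        differential_abundance(complete, "A", "B")


# -- recurrence filter ----------------------------------------------------------------


def records_for(protein_calls: dict[str, dict[str, str]], strains=None) -> pd.DataFrame:
    rows = []
    if strains is None:
        strains = sorted({s for calls in protein_calls.values() for s in calls})
    for prot, calls in protein_calls.items():
        for s in strains:
            rows.append(
                {"protein_id": prot, "strain_id": s, "direction": calls.get(s, "ns")}
            )
    return pd.DataFrame(rows)


def test_recurrence_filter_boundary_counts():
    strains = [f"S{i}" for i in range(20)]  # need = ceil(0.5 * 20) = 10
    calls = {
        "IN": {s: "up" for s in strains[:10]},
        "OUT": {s: "up" for s in strains[:9]},
        "DOWN": {s: "down" for s in strains[:12]},
    }
    ups, downs, conflicts = recurrence_filter(records_for(calls, strains=strains))
    assert ups == {"IN"}
    assert downs == {"DOWN"}
    assert conflicts == set()


def test_recurrence_filter_conflicts_excluded():
    strains = [f"S{i}" for i in range(4)]  # need = 2
    calls = {"X": {strains[0]: "up", strains[1]: "up", strains[2]: "down", strains[3]: "down"}}
    with pytest.warns(UserWarning, match="both directions"):
        ups, downs, conflicts = recurrence_filter(records_for(calls))
    assert ups == downs == set()
    assert conflicts == {"X"}


# -- CV profile and PCA -----------------------------------------------------------------


def test_cv_profile_closed_form():
    vals = np.array([[8.0, 12.0], [10.0, 10.0]])
    m = matrix_from(vals, ["A", "A"])
    cv, median = cv_profile(m, ["smp0", "smp1"])
    assert cv["P000"] == pytest.approx(np.std([8, 12], ddof=1) / 10.0, rel=1e-12)
    assert cv["P001"] == 0.0
    assert median == pytest.approx(cv.median())
    with pytest.raises(ValueError, match="at least 2"):
        cv_profile(m, ["smp0"])


def test_cv_profile_requires_two_observations(rng):
    vals = np.array([[8.0, np.nan, 12.0], [np.nan, np.nan, 5.0]])
    m = matrix_from(vals, ["A", "A", "A"])
    cv, _ = cv_profile(m, ["smp0", "smp1", "smp2"])
    assert list(cv.index) == ["P000"]  # P001 observed once -> dropped


def test_pca_samples_shape(rng):
    m = lognormal_matrix(rng, 100, ["A", "A", "B", "B"])
    coords = pca_samples(m, n_components=2)
    assert coords.shape == (4, 2)
    assert len(coords.attrs["explained_variance_ratio"]) == 2
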