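import dendropy
import numpy as np
import pandas as pd
import pytest

import fieldqsip as fq


@pytest.fixture(scope="session")
def tree20():
    return fq.simulate_tree(20, seed=11)


@pytest.fixture(scope="session")
def dataset_small():
    """60-taxon experiment at default noise (fixed seed)."""
    return fq.simulate_experiment(fq.SimConfig(n_taxa=60, seed=3))


@pytest.fixture(scope="session")
def results_small(dataset_small):
    return fq.EafModel(dataset_small).fit(n_boot=300, seed=1)


@pytest.fixture(scope="session")
def dataset_clean():
    """Noise-free experiment: exact abundances, no qPCR noise, no dropout."""
    cfg = fq.SimConfig(n_taxa=40, seed=9, qpcr_cv=0.0, exact_abundances=True,
                       detection_floor=0.0)
    return fq.simulate_experiment(cfg)


@pytest.fixture(scope="session")
def results_clean(dataset_clean):
    return fq.EafModel(dataset_clean).fit(n_boot=200, seed=2)


def star_tree(n, branch=1.0):
    newick = "(" + ",".join(f"T{i}:{branch}" for i in range(n)) + ");"
    return dendropy.Tree.get(data=newick, schema="newick")


def true_eaf_series(dataset, treatment):
    return pd.Series(np.asarray(dataset.truth["true_eaf"][treatment]),
                     index=dataset.truth["taxa"])


def build_dataset(tube_specs, densities):
    """Assemble a QsipDataset from explicit per-tube abundance profiles.

    ``tube_specs``: list of dicts with keys treatment, block, isotope,
    abund (taxa x fractions DataFrame), totals (per-fraction array).
    """
    frac_rows, cols = [], {}
    taxa = tube_specs[0]["abund"].index
    for spec in tube_specs:
        tube_id = f"{spec['treatment']}.B{spec['block']}.{spec['isotope']}"
        for j, rho in enumerate(densities):
            frac_rows.append({
                "tube_id": tube_id, "treatment": spec["treatment"],
                "block": spec["block"], "isotope": spec["isotope"],
                "fraction_idx": j + 1, "density_g_ml": rho,
                "total_16s_copies": spec["totals"][j],
            })
            cols[f"{tube_id}.F{j + 1}"] = spec["abund"].iloc[:, j].to_numpy()
    return fq.QsipDataset(fractions=pd.DataFrame(frac_rows),
                          counts=pd.DataFrame(cols, index=taxa))


def fake_eaf_results(rows):
    """EafResults carrying just an eaf_table (for response-function units).

    ``rows``: iterable of (taxon_id, treatment, mean_eaf) or dicts.
    """
    records = []
    for r in rows:
        if not isinstance(r, dict):
            r = {"taxon_id": r[0], "treatment": r[1], "mean_eaf": r[2]}
        r.setdefault("raw_mean_eaf", r["mean_eaf"])
        r.setdefault("ci_lo", r["mean_eaf"])
        r.setdefault("ci_hi", r["mean_eaf"])
        r.setdefault("n_blocks", 4)
        r.setdefault("truncated", False)
        r.setdefault("growing", r["mean_eaf"] > 0)
        records.append(r)
    table = pd.DataFrame(records)
    return fq.EafResults(model=None, eaf_table=table,
                         block_table=pd.DataFrame(
                             columns=["taxon_id", "treatment", "block",
                                      "w_light", "w_label", "eaf_raw",
                                      "light_fallback"]),
                         wad_table=pd.DataFrame(), n_boot=0, ci_level=0.9)
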