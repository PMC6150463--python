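import numpy as np
import pandas as pd
import pytest

import t2dclust as tc


@pytest.fixture(scope="session")
def planted_k3():
    """A K=3 planted model with its summary stats, matrix and doubled X."""
    model = tc.make_planted_model(k_true=3, seed=7)
    tables, truth = tc.gen_summary_stats(model)
    vtm = tc.build_matrix(model.manifest, tables)
    x = tc.split_signed(vtm.values)
    return {"model": model, "tables": tables, "truth": truth,
            "vtm": vtm, "x": x}


def match_components(w_est: pd.DataFrame, w_true: pd.DataFrame):
    """Pair estimated components with planted clusters by weight correlation."""
    from scipy.optimize import linear_sum_assignment

    corr = np.zeros((w_est.shape[1], w_true.shape[1]))
    for i, ce in enumerate(w_est.columns):
        for j, ct in enumerate(w_true.columns):
            a = w_est[ce].to_numpy()
            b = w_true.loc[w_est.index, ct].to_numpy()
            if a.std() == 0 or b.std() == 0:
                corr[i, j] = 0.0
            else:
                corr[i, j] = np.corrcoef(a, b)[0, 1]
    rows, cols = linear_sum_assignment(-corr)
    return list(zip(w_est.columns[rows], w_true.columns[cols]))


def membership_agreement(w_est: pd.DataFrame, cutoff: float,
                         w_true: pd.DataFrame) -> float:
    """Fraction of variant-cluster membership indicators that agree with truth."""
    pairs = match_components(w_est, w_true)
    agree = []
    for ce, ct in pairs:
        est = (w_est[ce] >= cutoff).to_numpy()
        true = (w_true.loc[w_est.index, ct] > 0).to_numpy()
        agree.append(np.mean(est == true))
    return float(np.mean(agree))
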