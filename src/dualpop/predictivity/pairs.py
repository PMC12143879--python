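"""Pair selection by rate product and rate-distribution matching."""

from __future__ import annotations

import numpy as np
import pandas as pd

LOG_RATE_BIN = 0.05  # log10 spikes/s


def top_pairs(
    unit_table: pd.DataFrame,
    n: int = 10_000,
) -> pd.DataFrame:
    """Cross-region pairs ranked by the product of mean rates.

    ``unit_table`` needs columns unit_id, region, session, mean_rate,
    width_class, peak_sign. Only wide-waveform units with negative-going
    peaks are eligible, and pairs are formed within session only. When
    fewer than ``n`` pairs exist, all are returned with a warning-free
    truncation. Each row is one undirected pair; both directed orderings
    share the row.
    """
    elig = unit_table[
        (unit_table["width_class"] == "wide") & (unit_table["peak_sign"] < 0)
    ]
    rows = []
    for session, grp in elig.groupby("session"):
        a = grp[grp["region"] == "A"]
        b = grp[grp["region"] == "B"]
        for _, ua in a.iterrows():
            for _, ub in b.iterrows():
                rows.append(
                    {
                        "session": session,
                        "unit_A": ua["unit_id"],
                        "unit_B": ub["unit_id"],
                        "rate_A": ua["mean_rate"],
                        "rate_B": ub["mean_rate"],
                        "product": ua["mean_rate"] * ub["mean_rate"],
                    }
                )
    pairs = pd.DataFrame(rows).sort_values("product", ascending=False)
    return pairs.head(n).reset_index(drop=True)


def _bin_index(rates: np.ndarray) -> np.ndarray:
    return np.floor(np.log10(np.maximum(rates, 1e-12)) / LOG_RATE_BIN).astype(int)


def match_rate_distributions(
    pairs: pd.DataFrame,
    unit_table: pd.DataFrame,
    swap_side: str = "A",
    seed: int = 0,
    max_iters: int = 100_000,
) -> pd.DataFrame:
    """Equalize the two regions' per-bin rate histograms by seeded swaps.

    Multiplicity of a unit equals its pair membership count. While some bin
    holds more ``swap_side`` cells than other-side cells, a random pair with
    a ``swap_side`` cell in such a bin and an other-side cell in a bin where
    the other side is overrepresented is chosen, and its ``swap_side`` cell
    is replaced by a same-session ``swap_side``-region cell from the other
    cell's bin (drawn with replacement). Terminates when bins match or no
    legal swap exists; each swap strictly reduces the total bin-count
    discrepancy.
    """
    rng = np.random.default_rng(seed)
    out = pairs.copy().reset_index(drop=True)
    other = "B" if swap_side == "A" else "A"
    region = swap_side

    # replacement candidates: eligible units per (session, bin)
    elig = unit_table[
        (unit_table["region"] == region)
        & (unit_table["width_class"] == "wide")
        & (unit_table["peak_sign"] < 0)
    ].copy()
    elig["bin"] = _bin_index(elig["mean_rate"].to_numpy())
    cand = {
        key: grp[["unit_id", "mean_rate"]].to_numpy()
        for key, grp in elig.groupby(["session", "bin"])
    }

    n_swaps = 0
    for _ in range(max_iters):
        bin_s = _bin_index(out[f"rate_{swap_side}"].to_numpy())
        bin_o = _bin_index(out[f"rate_{other}"].to_numpy())
        all_bins = np.union1d(bin_s, bin_o)
        count_s = {b: int((bin_s == b).sum()) for b in all_bins}
        count_o = {b: int((bin_o == b).sum()) for b in all_bins}
        over = [b for b in all_bins if count_s[b] > count_o[b]]
        under = {b for b in all_bins if count_o[b] > count_s[b]}
        if not over or not under:
            break
        # pairs with a swap-side cell in an overfull bin AND an other-side
        # cell in an underfull bin, for which a replacement exists
        legal = []
        for i in range(len(out)):
            if bin_s[i] in over and bin_o[i] in under:
                key = (out.at[i, "session"], bin_o[i])
                if key in cand:
                    legal.append(i)
        if not legal:
            break
        i = int(rng.choice(legal))
        key = (out.at[i, "session"], bin_o[i])
        pick = cand[key][rng.integers(len(cand[key]))]
        out.at[i, f"unit_{swap_side}"] = pick[0]
        out.at[i, f"rate_{swap_side}"] = pick[1]
        out.at[i, "product"] = out.at[i, "rate_A"] * out.at[i, "rate_B"]
        n_swaps += 1
    out.attrs["n_swaps"] = n_swaps
    return out
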