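"""The published barley cadmium-tolerance worked example.

The package ships the 18 curated lncRNA-mRNA pairs (12 distinct lncRNAs)
reported for the contrasting hull-less barley genotypes X178 (Cd-tolerant)
and X38 (Cd-sensitive), with each member's log2 fold change (Cd vs control)
in both genotypes.  Running the three-state rule, the genotype-contrast
classification and the key-pair selection over these printed fold changes
is the package's permanent golden test: the selection rule must retain all
18 pairs, and the state tallies must match the published ones.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .expression import call_state
from .screen import ToleranceCall, contrast_classify, select_key_pairs

#: the two lncRNAs with a non-null state in the tolerant genotype; the other
#: ten ("remaining") lncRNAs are unchanged there
_TOLERANT_RESPONSIVE = ("TCONS_00005624", "TCONS_00071028")

#: survey-level tallies reported for the same barley dataset: total novel
#: lncRNAs, lncRNAs with at least one target, and the positional partition of
#: the cis pairs (near-gene pairs split by side, overlap split into the six
#: positional subtypes)
PUBLISHED_SURVEY = {
    "n_lncrna": 8299,
    "n_lncrna_with_targets": 2571,
    "cis_downstream": 893,
    "cis_upstream": 664,
    "cis_overlap": 1802,
    "overlap_subtypes": {
        "AntiIntronic": 57, "AntiOverlapping": 21, "AntiSense": 173,
        "Intronic": 118, "Overlapping": 53, "Sense": 1380,
    },
}


def survey_consistency(survey: dict | None = None) -> dict:
    """Derived quantities of a survey-level report.

    Computes the share of lncRNAs with targets (percent, one decimal), the
    positional cis total (upstream + downstream + overlap) and the sum of the
    six overlap subtypes — the internal-consistency arithmetic any cis
    partition must satisfy.
    """
    s = PUBLISHED_SURVEY if survey is None else survey
    return {
        "lncrna_with_targets_percent": round(
            100.0 * s["n_lncrna_with_targets"] / s["n_lncrna"], 1
        ),
        "cis_positional_total": s["cis_downstream"] + s["cis_upstream"] + s["cis_overlap"],
        "overlap_subtype_total": sum(s["overlap_subtypes"].values()),
    }


def load_worked_example() -> pd.DataFrame:
    """The 18 curated pairs with both members' fold changes in both genotypes."""
    ref = resources.files("lncscreen").joinpath("data/barley_cd_key_pairs.tsv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def run_worked_example(lfc_min: float = 1.0) -> dict:
    """Apply the screen's rules to the worked example and tally the results.

    States come from the fold-change-only three-state rule (up iff
    log2fc >= +1, down iff <= -1, else unchanged); a pair is a key pair when
    its lncRNA is tolerance-linked and its target's state differs between
    genotypes.  Returns the retained pair table plus the summary tallies.
    """
    df = load_worked_example()

    def states_of(fc_tol: float, fc_sen: float) -> tuple[str, str]:
        return (call_state(fc_tol, lfc_min=lfc_min), call_state(fc_sen, lfc_min=lfc_min))

    calls: dict[str, ToleranceCall] = {}
    fc_rows = []
    for r in df.itertuples(index=False):
        for fid, fc_t, fc_s in (
            (r.lncrna_id, r.lnc_log2fc_tolerant, r.lnc_log2fc_sensitive),
            (r.target_id, r.target_log2fc_tolerant, r.target_log2fc_sensitive),
        ):
            st, ss = states_of(fc_t, fc_s)
            calls[fid] = ToleranceCall(fid, st, ss, contrast_classify(st, ss))
            fc_rows += [
                {"feature_id": fid, "genotype": "tolerant", "log2fc": fc_t},
                {"feature_id": fid, "genotype": "sensitive", "log2fc": fc_s},
            ]
    key = select_key_pairs(
        df[["lncrna_id", "target_id"]],
        calls.values(),
        pd.DataFrame(fc_rows).drop_duplicates(),
    )

    lnc_ids = list(dict.fromkeys(df["lncrna_id"]))
    lnc_states_tolerant = {i: calls[i].state_tolerant for i in lnc_ids}
    remaining_targets = [
        r.target_id for r in df.itertuples(index=False)
        if r.lncrna_id not in _TOLERANT_RESPONSIVE
    ]

    def tally(values) -> dict[str, int]:
        out = {"up": 0, "down": 0, "unchanged": 0}
        for v in values:
            out[v] += 1
        return out

    return {
        "key_pairs": key,
        "n_pairs": len(key),
        "n_lncrnas": int(key["lncrna_id"].nunique()),
        "lnc_states_tolerant": tally(lnc_states_tolerant.values()),
        "remaining_target_states_tolerant": tally(
            calls[t].state_tolerant for t in remaining_targets
        ),
        "remaining_target_states_sensitive": tally(
            calls[t].state_sensitive for t in remaining_targets
        ),
        "lnc_categories": {i: calls[i].category for i in lnc_ids},
    }
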