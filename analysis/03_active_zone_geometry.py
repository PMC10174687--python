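"""Functional AZ reconstruction and the two asynchronous populations.

Builds each bouton's AZ as the convex hull of its synchronous events,
normalizes every event's distance to the AZ center by the center-to-border
distance (+25 nm rim) along the same ray, and splits asynchronous events
into in-AZ (d_norm <= 1) and ectopic (d_norm > 1).  Also fits the
saturation of the in-AZ share with synchronous sampling.
"""

import pandas as pd
from common import RESULTS, analyzed, dataset

from azmap import (
    build_az_map,
    compare_distributions,
    filter_boutons,
    fraction_pct,
    in_az_asymptote,
    label_events,
    radial_profile,
)
from azmap.model import ASYNCHRONOUS, ECTOPIC, IN_AZ, SYNCHRONOUS


def main():
    sp, radial, az_map, _ = analyzed()
    radial.to_csv(RESULTS / "radial_profile.tsv", sep="\t", index=False)

    a = radial[radial["release_class"] == ASYNCHRONOUS]
    defined = a[a["location_class"].isin([IN_AZ, ECTOPIC])]
    n_in = int((defined["location_class"] == IN_AZ).sum())
    print(
        f"asynchronous events: {len(defined)} with defined location; "
        f"in-AZ {n_in} ({fraction_pct(n_in, len(defined))}%), "
        f"ectopic {len(defined) - n_in} "
        f"({fraction_pct(len(defined) - n_in, len(defined))}%)"
    )

    sync_d = radial.loc[radial["release_class"] == SYNCHRONOUS, "d_center_nm"].dropna()
    in_d = defined.loc[defined["location_class"] == IN_AZ, "d_center_nm"]
    d, p = compare_distributions(in_d, sync_d, "ks")
    print(
        f"in-AZ asynchronous vs synchronous distances: medians "
        f"{in_d.median():.0f} vs {sync_d.median():.0f} nm (KS D={d:.3f}, p={p:.2g})"
    )

    # saturation of the in-AZ share with the number of synchronous events
    ds, _ = dataset()
    ds = label_events(ds)
    all_ds, _ = filter_boutons(ds, "all")
    rad_all = radial_profile(all_ds, build_az_map(all_ds))
    rows = []
    for b, sub in rad_all.groupby("bouton_id"):
        asy = sub[(sub["release_class"] == ASYNCHRONOUS) & sub["d_norm"].notna()]
        if len(asy):
            rows.append(
                ((sub["release_class"] == SYNCHRONOUS).sum(),
                 (asy["location_class"] == IN_AZ).mean())
            )
    per_b = pd.DataFrame(rows, columns=["n_sync", "frac_in_az"])
    plateau, tau, means = in_az_asymptote(per_b)
    means.to_csv(RESULTS / "in_az_asymptote.tsv", sep="\t", index=False)
    print(
        f"in-AZ share saturates at {100 * plateau:.1f}% "
        f"(tau = {tau:.1f} synchronous events)"
    )
    print(f"wrote {RESULTS / 'radial_profile.tsv'} and in_az_asymptote.tsv")


if __name__ == "__main__":
    main()
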