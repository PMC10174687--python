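"""Temporal classification and bouton inclusion filters.

First post-stimulus frame -> synchronous; second frame -> asynchronous
unless the same bouton fired in the first frame of that stimulus
(excluded).  Boutons need >= 5 synchronous events for any analysis and
>= 10 classified events for spatial analyses.
"""

from common import RESULTS, dataset

from azmap import filter_boutons, label_events


def main():
    ds, _ = dataset()
    ds = label_events(ds)
    counts = ds.events["release_class"].value_counts()
    print("classification:")
    print(counts.to_string())

    _, audit_all = filter_boutons(ds, "all")
    _, audit_spatial = filter_boutons(ds, "spatial")
    audit = audit_all.merge(
        audit_spatial[["bouton_id", "kept"]].rename(columns={"kept": "kept_spatial"}),
        on="bouton_id",
    ).rename(columns={"kept": "kept_all"})
    audit.to_csv(RESULTS / "bouton_audit.tsv", sep="\t", index=False)
    print(
        f"boutons: {len(audit)} total, {audit['kept_all'].sum()} pass the "
        f">=5-synchronous filter, {audit['kept_spatial'].sum()} also pass the "
        f">=10-event spatial filter"
    )
    print(f"wrote {RESULTS / 'bouton_audit.tsv'}")


if __name__ == "__main__":
    main()
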