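"""Generate the synthetic study dataset and describe its composition.

Writes the event table and the ground-truth table under results/; traces
are regenerated deterministically by the later drivers (same seed) instead
of being stored.
"""

from common import RESULTS, dataset

from azmap import write_events


def main():
    ds, gt = dataset()
    write_events(ds, RESULTS / "events.csv")
    gt.events.to_csv(RESULTS / "ground_truth.csv", index=False)
    by_class = gt.events["true_class"].value_counts()
    print(f"generated {ds.n_events} events in {len(ds.boutons)} boutons")
    print(by_class.to_string())
    print(
        f"true ectopic fraction among asynchronous: "
        f"{gt.events.loc[gt.events['true_class'] == 'asynchronous', 'true_ectopic'].mean():.3f}"
    )
    print(f"wrote {RESULTS / 'events.csv'} and ground_truth.csv")


if __name__ == "__main__":
    main()
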