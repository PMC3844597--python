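import numpy as np
import pandas as pd
import pytest

import drugsig as ds


def make_matrix(values, probe_ids=None, sample_meta=None):
    """Build a small ExpressionMatrix from a 2-D array and metadata rows.

    ``sample_meta`` is a list of (sample_id, drug, time_h, replicate,
    batch, is_vehicle) tuples; defaults produce a one-batch two-group
    design sized to the array.
    """
    values = np.asarray(values, dtype=float)
    n_probes, n_samples = values.shape
    if probe_ids is None:
        probe_ids = [f"p{i:03d}" for i in range(n_probes)]
    if sample_meta is None:
        sample_meta = [
            (f"s{j}", "drugA" if j < n_samples // 2 else "veh", 1.0,
             j + 1, "b1", j >= n_samples // 2)
            for j in range(n_samples)
        ]
    ids = [m[0] for m in sample_meta]
    sheet = pd.DataFrame(
        [m[1:] for m in sample_meta],
        index=pd.Index(ids, name="sample_id"),
        columns=["drug", "time_h", "replicate", "batch", "is_vehicle"],
    )
    vals = pd.DataFrame(values, index=pd.Index(probe_ids, name="probe_id"), columns=ids)
    return ds.ExpressionMatrix(values=vals, samples=sheet)


def shared_mechanism_config(seed, noise_sd=0.3, amplitude=2.0, n_probes=160):
    """Eight drugs over four mechanisms, two drugs per mechanism.

    Used for held-out mechanism-recovery simulations: any single drug
    can be left out and its mechanism remains engaged by its partner.
    """
    mechs = ["m1", "m2", "m3", "m4"]
    peaks = (1.0, 2.0, 4.0, 8.0)
    drugs = [
        ds.DrugSpec(
            name=f"d{i + 1}",
            mechanisms={mechs[i // 2]: 1.0},
            control="veh",
            peak_time_h=peaks[i % 4],
            amplitude=amplitude,
        )
        for i in range(8)
    ]
    drugs.append(ds.DrugSpec(name="veh", is_vehicle=True))
    size = max(2, (n_probes * 3) // 16)  # 4 modules covering ~3/4 of probes
    return ds.SyntheticConfig(
        n_probes=n_probes,
        mechanisms=mechs,
        drugs=drugs,
        network_sizes=(size, size, size, size),
        network_mechanisms=("m1", "m2", "m3", "m4"),
        noise_sd=noise_sd,
        seed=seed,
    )


@pytest.fixture(scope="session")
def study_run():
    """One moderate study-shaped experiment shared across read-only tests."""
    cfg = ds.study_config(n_probes=600, network_sizes=(40, 20, 15), seed=11)
    em, truth = ds.generate_experiment(cfg)
    fct = ds.fold_changes(em, vehicle_map=truth.vehicle_map)
    scores = ds.g2m(fct)
    return {"config": cfg, "em": em, "truth": truth, "fct": fct, "scores": scores}
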