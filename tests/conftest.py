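import numpy as np
import pytest

from assocnet.io import (
    DUAL,
    SINGLE,
    ExperimentSet,
    ExpressionMatrix,
    ProbeGeneMap,
)


@pytest.fixture
def small_dual_matrix() -> ExpressionMatrix:
    """3 probes x 4 samples of log-ratio values, no missing cells."""
    rng = np.random.default_rng(7)
    return ExpressionMatrix(
        experiment_id="E1",
        organism_id="org",
        channel=DUAL,
        probe_ids=("p1", "p2", "p3"),
        sample_ids=("s1", "s2", "s3", "s4"),
        values=rng.normal(size=(3, 4)),
    )


@pytest.fixture
def identity_probe_map() -> ProbeGeneMap:
    return ProbeGeneMap(entries={f"p{i}": f"g{i}" for i in range(1, 10)})


def make_experiment(
    experiment_id: str,
    n_probes: int,
    n_samples: int,
    channel: str = DUAL,
    organism_id: str = "org",
    seed: int = 0,
    values: np.ndarray | None = None,
) -> ExpressionMatrix:
    if values is None:
        rng = np.random.default_rng(seed)
        values = rng.normal(size=(n_probes, n_samples))
        if channel == SINGLE:
            values = 2.0 ** (values + 8.0)
    return ExpressionMatrix(
        experiment_id=experiment_id,
        organism_id=organism_id,
        channel=channel,
        probe_ids=tuple(f"p{i}" for i in range(1, n_probes + 1)),
        sample_ids=tuple(f"s{j}" for j in range(1, n_samples + 1)),
        values=values,
    )


def make_organism(
    organism_id: str,
    n_experiments: int,
    n_probes: int = 5,
    n_samples: int = 4,
    channel: str = DUAL,
) -> ExperimentSet:
    return ExperimentSet(
        organism_id=organism_id,
        experiments=tuple(
            make_experiment(
                f"{organism_id}_E{k}",
                n_probes,
                n_samples,
                channel=channel,
                organism_id=organism_id,
                seed=k,
            )
            for k in range(n_experiments)
        ),
    )
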