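import pytest

from mirstage._engines import get_engine
from mirstage._fio import write_fasta
from mirstage.pipeline import PipelineConfig, run_pipeline
from mirstage.synthio import (
    SyntheticConfig,
    generate,
    make_transcripts,
    write_dataset,
)

#: compact dataset for unit/property tests
SMALL_CONFIG = dict(
    seed=5,
    genome_length=150_000,
    n_known_precursors=6,
    n_novel_precursors=2,
    library_sizes=(2000, 2000, 2000),
    de_spec=((2, 1, 2.0), (3, 2, -2.0)),
)

#: study-scale dataset: 200 kb genome, 20 known + 10 novel planted
#: precursors, three libraries of 1e5 reads
FULL_CONFIG = dict(seed=7)


@pytest.fixture(scope="session")
def engine():
    return get_engine("builtin")


@pytest.fixture(scope="session")
def small_dataset():
    return generate(SyntheticConfig(**SMALL_CONFIG))


@pytest.fixture(scope="session")
def small_paths(small_dataset, tmp_path_factory):
    out = tmp_path_factory.mktemp("small_data")
    paths = write_dataset(small_dataset, out)
    txs, sites = make_transcripts(small_dataset)
    paths["transcripts"] = out / "transcripts.fa"
    write_fasta(paths["transcripts"], txs.items())
    paths["sites"] = sites
    return paths


def _pipeline_config(paths, outdir, **kw):
    return PipelineConfig(
        genome=str(paths["genome"]),
        features=str(paths["features"]),
        mature=str(paths["mature"]),
        hairpin=str(paths["hairpin"]),
        mature_windows=str(paths["windows"]),
        fastqs=[str(paths[f"reads_{i}"]) for i in range(3)],
        output_dir=str(outdir),
        **kw,
    )


@pytest.fixture(scope="session")
def small_report(small_paths, tmp_path_factory):
    out = tmp_path_factory.mktemp("small_out")
    cfg = _pipeline_config(
        small_paths, out, transcripts=str(small_paths["transcripts"])
    )
    return run_pipeline(cfg)


@pytest.fixture(scope="session")
def full_dataset():
    return generate(SyntheticConfig(**FULL_CONFIG))


@pytest.fixture(scope="session")
def full_run(full_dataset, tmp_path_factory):
    """Study-scale end-to-end run; returns (dataset, report, wall seconds)."""
    import time

    data_dir = tmp_path_factory.mktemp("full_data")
    out_dir = tmp_path_factory.mktemp("full_out")
    t0 = time.perf_counter()
    paths = write_dataset(full_dataset, data_dir)
    cfg = _pipeline_config(paths, out_dir)
    report = run_pipeline(cfg)
    elapsed = time.perf_counter() - t0
    return full_dataset, report, elapsed
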