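import numpy as np
import pandas as pd
import pytest

import trilayer as tl


def make_gtf(path, lines):
    path.write_text("\n".join(lines) + "\n")
    return path


def gtf_exon(chrom, start, end, gene, tx, strand="+"):
    return (
        f"{chrom}\tsrc\texon\t{start}\t{end}\t.\t{strand}\t.\t"
        f'gene_id "{gene}"; transcript_id "{tx}";'
    )


@pytest.fixture
def overlap_model():
    """Two transcripts of one gene: T1 spans 100-300, T2 spans 200-400."""
    model = tl.AnnotationModel(
        genes={"G1": tl.Gene("G1", "chr1")},
        transcripts={
            "T1": tl.Transcript("T1", "G1", ((100, 300),)),
            "T2": tl.Transcript("T2", "G1", ((200, 400),)),
        },
    )
    return tl.flatten_exonic_regions(model)


@pytest.fixture(scope="session")
def mixed_cohort():
    """Small cohort with one event of each kind, reused where truth is needed."""
    spec = tl.CohortSpec(
        n_patients=12,
        n_genes=40,
        seed=21,
        planted_events=[
            tl.PlantedEvent("gene_de", 6.0),
            tl.PlantedEvent("transcript_switch", 4.0),
            tl.PlantedEvent("exon_de", 4.0),
        ],
    )
    return tl.generate_cohort(spec)


@pytest.fixture
def paired_metadata():
    def build(n_patients, covariates=None):
        rows = {
            "patient_id": [f"P{i:03d}" for i in range(n_patients) for _ in range(2)],
            "tissue": ["tumor", "normal"] * n_patients,
        }
        if covariates:
            for name, values in covariates.items():
                rows[name] = [values[i] for i in range(n_patients) for _ in range(2)]
        idx = [f"P{i:03d}{s}" for i in range(n_patients) for s in ("T", "N")]
        return tl.SampleMetadata(pd.DataFrame(rows, index=pd.Index(idx, name="sample_id")))

    return build
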