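"""Convert PDH measurements to AnIML and bundle them into a COMBINE archive.

Synthetic PDH fixtures (one per mesophase) are written to a scratch
directory, converted to a single AnIML document with one sample and one
experiment step per file, and packaged together with the raw files into an
OMEX-style ZIP with manifest and per-file RDF metadata.
"""

import tempfile
from pathlib import Path

from saxskit import synth, workflow
from saxskit.omex import read_archive
from saxskit.readers import enumerate_pdh

base = Path(tempfile.mkdtemp(prefix="saxskit_example_"))
synth.write_fixture_set(base / "pdh", seeds=[1])
pdh_files = enumerate_pdh(base / "pdh")
print(f"{len(pdh_files)} PDH files:", ", ".join(p.name for p in pdh_files))

config = workflow.RunConfig(timestamp="2024-01-01T00:00:00Z")
animl = base / "measurements.animl"
doc = workflow.convert(pdh_files, animl, config)
print(f"AnIML document: {len(doc.sample_set)} samples, "
      f"{len(doc.list_series_ids())} series")

archive = workflow.package(animl, pdh_files, base / "dataset.zip", config)
entries, _ = read_archive(archive)
master = next(e for e in entries if e.master)
print(f"archive {archive.name}: {len(entries)} manifest entries, "
      f"master = {master.location}")
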