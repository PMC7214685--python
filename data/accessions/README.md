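# Local structure entries

Place local copies of public structure entries here as `<CODE>.pdb` or
`<CODE>.cif` (e.g. `2NA7.cif`, `3TJE.cif`, `3QD6.cif`, `4MSV.cif`).

The test suite and CLI never download anything by default; on a
network-enabled machine you can populate this directory with, for example:

    curl -O https://files.rcsb.org/download/2NA7.cif

or by passing `--fetch` to the CLI subcommands that accept accessions.
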