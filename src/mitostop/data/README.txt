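Place the mouse mtDNA reference here as NC_005089.gb (GenBank flat
file with CDS features). Fetch it once with:
    mitostop fetch-reference --email you@example.org
The sequence is not redistributed with the package.
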