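# alias	canonical
omeprazole	Omeprazole
prilosec	Omeprazole
losec	Omeprazole
esomeprazole	Esomeprazole
nexium	Esomeprazole
lansoprazole	Lansoprazole
prevacid	Lansoprazole
pantoprazole	Pantoprazole
protonix	Pantoprazole
rabeprazole	Rabeprazole
aciphex	Rabeprazole
pariet	Rabeprazole
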