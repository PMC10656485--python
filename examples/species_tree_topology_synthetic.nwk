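((((Halobacterium,Methanosarcina),(Sulfolobus,(Nitrososphaera,Thaumarchaeon))),((Lokiarchaeum,Heimdallarchaeum),((Homo_nuclear,Saccharomyces_nuclear),(Arabidopsis_nuclear,Cyanidioschyzon_nuclear)))),((((Escherichia,Rickettsia),((Homo_mito,Saccharomyces_mito),(Arabidopsis_mito,Cyanidioschyzon_mito))),(Bacillus,Chloroflexus)),((Gloeomargarita,Synechocystis),(Arabidopsis_plastid,Cyanidioschyzon_plastid))));
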