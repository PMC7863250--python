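# gmoget default donor registry
# CODE	category	scientific name
AGABB	species	Agaricus bisporus
ARATH	species	Arabidopsis thaliana
BACTK	species	Bacillus thuringiensis subsp. kurstaki
BACTU	species	Bacillus thuringiensis
BRANA	species	Brassica napus
ECOLI	species	Escherichia coli
HORVU	species	Hordeum vulgare
MAIZE	species	Zea mays
ORYSA	species	Oryza sativa
PEA	species	Pisum sativum
RHIRD	species	Rhizobium radiobacter
SOLLC	species	Solanum lycopersicum
SOLTU	species	Solanum tuberosum
SOYBN	species	Glycine max
STRHY	species	Streptomyces hygroscopicus
STRVR	species	Streptomyces viridochromogenes
TOBAC	species	Nicotiana tabacum
WHEAT	species	Triticum aestivum
CaMV	virus	Cauliflower mosaic virus
FMV	virus	Figwort mosaic virus
TMV	virus	Tobacco mosaic virus
SYNTH	synthetic	synthetic construct
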