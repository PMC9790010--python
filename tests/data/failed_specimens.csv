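unique_id,color,poly_acronym,polymer,structure,category,description,parent_grp,location_collected
BIOL011,brown,,keratin,fragment,biological,"hawksbill turtle, Eretmochelys imbricata, scute",biological,Hawaii
BIOL018,red,,algin,sheet,biological,Cryptopleura sp. algae blade,biological,"Monterey Bay, CA"
BIOL019,green,,algin,sheet,biological,Ulva sp. algae blade,biological,"Monterey Bay, CA"
BIOL020,brown,,cellulose,sheet,biological,cardboard box,biological,commercial
BIOL026,white,,calcium carbonate,fragment,biological,"Pacific purple urchin, Strongylocentrotus purpuratus, shell",biological,"Monterey Bay, CA"
BIOL027,brown,,keratin,fur,biological,"sea otter, Enhydra lutris, pup pelt SO # 1971-91",biological,"Monterey Bay, CA"
BIOL029,"gray, red before drying",,"algin, calcium carbonate",fragment,biological,Corallina sp. calcareous red algae,biological,"Monterey Bay, CA"
BIOL030,brown green,,algin,sheet,biological,"Egregia menziesii, feather boa kelp",biological,"Monterey Bay, CA"
BIOL032,dark green brown,,algin,fragment,biological,"Nereocystis luetkeana, bull kelp neumatocyst",biological,"Monterey Bay, CA"
PLAS039,black,PMMA,acrylic,sheet,pristine anthropogenic,"optix acrylic 2025, alpha packaging",consumer,commercial
PLAS053,clear,PE,polyethylene,sheet,pristine anthropogenic,costume bag,consumer,commercial
PLAS076,black,PVC,vinyl,flooring,pristine anthropogenic,Vinyl flooring sample,building material,commercial
PLAS192,gray,CPVC,chlorinated polyvinyl chloride,sheet,pristine anthropogenic,McMaster Carr samples,industrial,commercial
PLAS196,gray,PAI,polyamide-imide,sheet,pristine anthropogenic,Torlon samples,industrial,commercial
PLAS229,amber,MDI,methylene diphenyl diisocyanate,resin,pristine anthropogenic,gorilla glue,consumer,commercial
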