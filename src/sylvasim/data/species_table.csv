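species,area_km2,volume_Mm3,wood_type
Quercus robur,21180,294,hardwood
Quercus petraea,16140,268,hardwood
Quercus pubescens,14480,93,hardwood
Quercus ilex,6560,23,hardwood
Fagus sylvatica,14080,253,hardwood
Castanea sativa,7280,109,hardwood
Carpinus betulus,5500,83,hardwood
Fraxinus excelsior,6530,83,hardwood
Other hardwood,19460,420,hardwood
Pinus pinaster,10520,94,softwood
Pinus sylvestris,9160,91,softwood
Pinus laricio,1900,,softwood
Pinus nigra,1800,10,softwood
Pinus halepensis,2390,17,softwood
Abies alba,5880,180,softwood
Picea abies,5670,131,softwood
Pseudotsuga menziesii,3990,71,softwood
Other softwood,3170,296,softwood
Total hardwood,111210,1626,hardwood
Total softwood,44480,890,softwood
Total,155690,2516,
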