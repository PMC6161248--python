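name,hmdb_id,class,molecular_weight,internal_standard,process_efficiency,default_dilution
2-Aminoisobutyrate,HMDB0001906,Alpha Amino Acids and Derivatives,103.12,IS01,1.0,1
4-l-Hydroxyproline,HMDB0000725,Alpha Amino Acids and Derivatives,131.13,IS01,1.0,1
5-Hydroxytryptophan,HMDB0000472,Alpha Amino Acids and Derivatives,220.22,IS01,1.0,1
ADMA,HMDB0001539,Alpha Amino Acids and Derivatives,202.25,IS01,1.0,1
Alanine,HMDB0000161,Alpha Amino Acids and Derivatives,89.09,IS01,1.0,1
Aminoadipate,HMDB0000510,Alpha Amino Acids and Derivatives,161.16,IS01,1.0,1
Arginine,HMDB0000517,Alpha Amino Acids and Derivatives,174.20,IS01,1.0,1
Asparagine,HMDB0000168,Alpha Amino Acids and Derivatives,132.12,IS01,1.0,1
Aspartate,HMDB0000191,Alpha Amino Acids and Derivatives,133.10,IS01,1.0,1
Betaine,HMDB0000043,Alpha Amino Acids and Derivatives,117.15,IS01,1.0,1
Citrulline,HMDB0000904,Alpha Amino Acids and Derivatives,175.19,IS01,1.0,1
Creatine,HMDB0000064,Alpha Amino Acids and Derivatives,131.13,IS01,1.0,1
Creatinine,HMDB0000562,Alpha Amino Acids and Derivatives,113.12,IS01,1.0,1
Cystathionine,HMDB0000099,Alpha Amino Acids and Derivatives,222.26,IS01,1.0,1
Dimethylglycine,HMDB0000092,Alpha Amino Acids and Derivatives,103.12,IS01,1.0,1
GABA,HMDB0000112,Alpha Amino Acids and Derivatives,103.12,IS01,1.0,1
G-Glutamylcysteine,HMDB0001049,Alpha Amino Acids and Derivatives,250.29,IS01,1.0,1
Glutamate,HMDB0000148,Alpha Amino Acids and Derivatives,147.13,IS01,1.0,1
Glutamine,HMDB0000641,Alpha Amino Acids and Derivatives,146.14,IS01,1.0,1
Glutathione,HMDB0000125,Alpha Amino Acids and Derivatives,307.32,IS01,1.0,1
Glycine,HMDB0000123,Alpha Amino Acids and Derivatives,75.07,IS01,1.0,1
Guanidoacetate,HMDB0000128,Alpha Amino Acids and Derivatives,117.11,IS01,1.0,1
Histidine,HMDB0000177,Alpha Amino Acids and Derivatives,155.15,IS01,1.0,1
Homocysteine,HMDB0000742,Alpha Amino Acids and Derivatives,135.18,IS01,1.0,1
Homoserine,HMDB0000719,Alpha Amino Acids and Derivatives,119.12,IS01,1.0,1
Hydroxykynurenine,HMDB0000732,Alpha Amino Acids and Derivatives,224.21,IS01,1.0,1
Isoleucine,HMDB0000172,Alpha Amino Acids and Derivatives,131.17,IS01,1.0,1
Kynurenine,HMDB0000684,Alpha Amino Acids and Derivatives,208.21,IS01,1.0,1
Leucine,HMDB0000687,Alpha Amino Acids and Derivatives,131.17,IS01,1.0,1
Lysine,HMDB0000182,Alpha Amino Acids and Derivatives,146.19,IS01,1.0,1
Methionine,HMDB0000696,Alpha Amino Acids and Derivatives,149.21,IS01,1.0,1
Ornithine,HMDB0000214,Alpha Amino Acids and Derivatives,132.16,IS01,1.0,1
Phenylalanine,HMDB0000159,Alpha Amino Acids and Derivatives,165.19,IS01,1.0,1
Proline,HMDB0000162,Alpha Amino Acids and Derivatives,115.13,IS01,1.0,1
SDMA,HMDB0003334,Alpha Amino Acids and Derivatives,202.25,IS01,1.0,1
Serine,HMDB0000187,Alpha Amino Acids and Derivatives,105.09,IS01,1.0,1
Threonine,HMDB0000167,Alpha Amino Acids and Derivatives,119.12,IS01,1.0,1
Tryptophan,HMDB0000929,Alpha Amino Acids and Derivatives,204.23,IS01,1.0,1
Tyrosine,HMDB0000158,Alpha Amino Acids and Derivatives,181.19,IS01,1.0,1
Valine,HMDB0000883,Alpha Amino Acids and Derivatives,117.15,IS01,1.0,1
3-Hydroxanthranilate,HMDB0001476,Benzoic Acids and Derivatives,153.14,IS01,1.0,1
Hippurate,HMDB0000714,Benzoic Acids and Derivatives,179.17,IS01,1.0,1
Carnosine,HMDB0000033,Beta Amino Acids and Derivatives,226.23,IS02,1.0,1
Pantothenate,HMDB0000210,Beta Amino Acids and Derivatives,219.23,IS02,1.0,1
Chenodeoxycholate,HMDB0000518,"Bile Acids, Alcohols and Derivatives",392.57,IS02,1.0,1
Cholate,HMDB0000619,"Bile Acids, Alcohols and Derivatives",408.57,IS02,1.0,1
Glycocholate,HMDB0000138,"Bile Acids, Alcohols and Derivatives",465.62,IS02,1.0,1
Taurochenodesoxycholate,HMDB0000951,"Bile Acids, Alcohols and Derivatives",499.70,IS02,1.0,1
d-Ribose-5-P,HMDB0001548,Carbohydrates and Carbohydrate Conjugates,230.11,IS03,1.0,1
Glyceraldehyde,HMDB0001051,Carbohydrates and Carbohydrate Conjugates,90.08,IS03,1.0,1
Sucrose,HMDB0000258,Carbohydrates and Carbohydrate Conjugates,342.30,IS03,1.0,1
Spermidine,HMDB0001257,Dialkylamines,145.25,IS03,1.0,1
Succinate,HMDB0000254,Dicarboxylic Acids and Derivatives,118.09,IS04,1.0,1
Acetylcarnitine,HMDB0000201,Fatty Acyls,203.24,IS04,1.0,1
Decanoylcarnitine,HMDB0000651,Fatty Acyls,315.45,IS04,1.0,1
Hexanoylcarnitine,HMDB0000705,Fatty Acyls,259.34,IS04,1.0,1
Isobutyrylcarnitine,HMDB0000736,Fatty Acyls,231.29,IS04,1.0,1
Isovalerylcarnitine,HMDB0000688,Fatty Acyls,245.32,IS04,1.0,1
Octanoylcarnitine,HMDB0000791,Fatty Acyls,287.40,IS04,1.0,1
Propionylcarnitine,HMDB0000824,Fatty Acyls,217.26,IS04,1.0,1
Folate,HMDB0000121,Folates,441.40,IS05,1.0,1
Glucuronate,HMDB0000127,Glucuronic Acid and Derivatives,194.14,IS05,1.0,1
1-Methylhistamine,HMDB0000898,Imidazoles,125.17,IS06,1.0,1
Allantoin,HMDB0000462,Imidazoles,158.12,IS06,1.0,1
5-Hydroxyindoleacetate,HMDB0000763,Indoles and Derivatives,191.18,IS06,1.0,1
Acetoacetate,HMDB0000060,Keto Acids and Derivatives,102.09,IS07,1.0,1
Phosphoethanolamine,HMDB0000224,Organic Phosphoric Acids and Derivatives,141.06,IS07,1.0,1
Taurine,HMDB0000251,Organosulfonic Acids,125.15,IS08,1.0,1
Taurocholate,HMDB0000036,Organosulfonic Acids,515.70,IS08,1.0,1
Trimethylamine N-oxide,HMDB0000925,Oxides,75.11,IS08,1.0,1
Homogentisate,HMDB0000130,Phenols,168.15,IS09,1.0,1
Normetanephrine,HMDB0000819,Phenols,183.20,IS09,1.0,1
Neopterin,HMDB0000845,Pteridines and Derivatives,253.21,IS09,1.0,1
Adenine,HMDB0000034,Purines and Derivatives,135.13,IS10,1.0,1
Adenosine,HMDB0000050,Purines and Derivatives,267.24,IS10,1.0,1
AMP,HMDB0000045,Purines and Derivatives,347.22,IS10,1.0,1
cAMP,HMDB0000058,Purines and Derivatives,329.21,IS10,1.0,1
cGMP,HMDB0001314,Purines and Derivatives,345.21,IS10,1.0,1
Guanosine,HMDB0000133,Purines and Derivatives,283.24,IS10,1.0,1
Hypoxanthine,HMDB0000157,Purines and Derivatives,136.11,IS10,1.0,1
IMP,HMDB0000175,Purines and Derivatives,348.21,IS10,1.0,1
Inosine,HMDB0000195,Purines and Derivatives,268.23,IS10,1.0,1
Xanthine,HMDB0000292,Purines and Derivatives,152.11,IS10,1.0,1
Xanthosine,HMDB0000299,Purines and Derivatives,284.23,IS10,1.0,1
4-Pyridoxate,HMDB0000017,Pyridines and Derivatives,183.16,IS10,1.0,1
Cotinine,HMDB0001046,Pyridines and Derivatives,176.22,IS10,1.0,1
NAD,HMDB0000902,Pyridines and Derivatives,663.43,IS10,1.0,1
Niacinamide,HMDB0001406,Pyridines and Derivatives,122.12,IS10,1.0,1
Nicotinate,HMDB0001488,Pyridines and Derivatives,123.11,IS10,1.0,1
Pyridoxine,HMDB0000239,Pyridines and Derivatives,169.18,IS10,1.0,1
Cytidine,HMDB0000089,Pyrimidines and Derivatives,243.22,IS11,1.0,1
Cytosine,HMDB0000630,Pyrimidines and Derivatives,111.10,IS11,1.0,1
Deoxycytidine,HMDB0000014,Pyrimidines and Derivatives,227.22,IS11,1.0,1
Deoxyuridine,HMDB0000012,Pyrimidines and Derivatives,228.20,IS11,1.0,1
Orotate,HMDB0000226,Pyrimidines and Derivatives,156.10,IS11,1.0,1
UDP Glucose,HMDB0000286,Pyrimidines and Derivatives,566.30,IS11,1.0,1
Uracil,HMDB0000300,Pyrimidines and Derivatives,112.09,IS11,1.0,1
Carnitine,HMDB0000062,Quaternary Ammonium Salts,161.20,IS12,1.0,1
Choline,HMDB0000097,Quaternary Ammonium Salts,104.17,IS12,1.0,1
Kynurenate,HMDB0000715,Quinolines and Derivatives,189.17,IS12,1.0,1
Myo-inositol,HMDB0000211,Sugar Alcohols,180.16,IS12,1.0,1
Sorbitol,HMDB0000247,Sugar Alcohols,182.17,IS12,1.0,1
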