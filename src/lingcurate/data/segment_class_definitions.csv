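id,origin_tag,predicate,description
D-PH4WA-01,WALS-enriching,type=C & place=uvular,uvulars
D-PH4WA-02,WALS-enriching,type=C & sonorant=yes & glottalized=yes,glottalized resonants
D-PH4WA-03,WALS-enriching,type=C & lateral=yes & sonorant=no,lateral obstruents
D-PH4WA-04,WALS-enriching,type=C & manner=nasal,nasals
D-PH4WA-06,WALS-enriching,manner=fricative,fricatives
D-PH4WA-07,WALS-enriching,manner=nasal & place=velar,velar nasals
D-PH4WA-08,WALS-enriching,type=V & nasalized=yes,nasalized vowels
D-PH4WA-09,WALS-enriching,type=V & front=yes & round=yes,front round vowels
D-PH4WA-10,WALS-enriching,place=interdental,interdentals
D-PH4WA-11,WALS-enriching,place=labial-velar,labial velars
D-PH4WA-12,WALS-enriching,place=pharyngeal | place=epiglottal,pharyngeal epiglottals
D-PH4WA-13,WALS-enriching,(place=dental | place=alveolar) & manner=approximant & lateral=yes & voiced=yes,dental alveolar voiced lateral approximant
D-PH4WA-14,WALS-enriching,manner=implosive,implosives
D-PH4WA-15,WALS-enriching,type=C & ejective=yes,ejectives
D-PH4WA-16,WALS-enriching,manner=click,clicks
D-PH4WA-17,WALS-enriching,type=T,tone
D-PH4WA-18,WALS-enriching,place=bilabial,bilabials
D-PHOIBLEBAF-01,independent,manner=affricate,affricates
D-PHOIBLEBAF-02,independent,type=C & aspirated=yes,aspirated consonants
D-PHOIBLEBAF-03,independent,manner=fricative & aspirated=yes,aspirated fricatives
D-PHOIBLEBAF-04a,independent,type=V & breathy=yes,breathy vowels
D-PHOIBLEBAF-04b,independent,type=C & breathy=yes,breathy consonants
D-PHOIBLEBAF-05a,independent,type=V & creaky=yes,creaky vowels
D-PHOIBLEBAF-05b,independent,type=C & creaky=yes,creaky consonants
D-PHOIBLEBAF-06,independent,manner=glide,glides
D-PHOIBLEBAF-07,independent,manner=trill | manner=tap | (manner=approximant & lateral=yes),liquids
D-PHOIBLEBAF-08,independent,type=C & long=yes,long consonants
D-PHOIBLEBAF-09,independent,type=V & long=yes,long vowels
D-PHOIBLEBAF-10,independent,place=palatal & lateral=yes,palatal laterals
D-PHOIBLEBAF-11,independent,manner=stop & aspirated=yes,aspirated stops
D-PHOIBLEBAF-12,independent,type=C & labialized=yes,labialized consonants
D-PHOIBLEBAF-13,independent,sonorant=no & (place=palatal | palatalized=yes),palatal and palatalized obstruents
D-PHOIBLEBAF-14,independent,type=C & sonorant=yes & (place=palatal | palatalized=yes),palatal and palatalized sonorants
D-PHOIBLEBAF-16,independent,strident=yes,stridents
D-PHOIBLEBAF-17,independent,lateral=yes,laterals
D-PHOIBLEBAF-18,independent,manner=tap,taps
D-PHOIBLEBAF-19,independent,place=labiodental,labiodentals
D-PHOIBLEBAF-20,independent,manner=trill & (place=dental | place=alveolar | place=retroflex),coronal trills
D-PHOIBLEBAF-22,independent,manner=trill & place=uvular,uvular trills
D-PHOIBLEBAF-23,independent,place=alveolar & manner=approximant & lateral=no,alveolar approximants
D-PHOIBLEBAF-24,independent,type=C & place=retroflex,retroflex consonants
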