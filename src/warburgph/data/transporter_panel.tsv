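symbol	family	role	included	exclusion_reason
SLC4A1AP	SLC4	acid_loader	True	
SLC4A2	SLC4	acid_loader	True	
SLC4A3	SLC4	acid_loader	True	
SLC26A6	SLC26	acid_loader	True	
ATP6V0B	ATP6V	acid_loader	True	
ATP6V0C	ATP6V	acid_loader	True	
SLC4A4	SLC4	acid_extruder	True	
SLC4A9	SLC4	acid_extruder	True	
SLC9A2	SLC9	acid_extruder	True	
SLC9A3	SLC9	acid_extruder	True	
SLC9A4	SLC9	acid_extruder	True	
SLC9A9	SLC9	acid_extruder	True	
SLC26A9	SLC26	acid_extruder	True	
SLC16A1	SLC16	lactate_exporter	True	
SLC16A3	SLC16	lactate_exporter	True	
SLC4A1	SLC4	acid_loader	False	expressed only in kidney samples
SLC4A5	SLC4	acid_extruder	False	expressed only in thyroid samples
SLC4A6	SLC4	acid_extruder	False	transporter not identified
SLC4A7	SLC4	acid_extruder	False	also localized to focal adhesion sites
SLC4A8	SLC4	acid_extruder	False	not expressed in any samples
SLC4A10	SLC4	acid_extruder	False	not expressed in any samples
SLC4A11	SLC4	acid_extruder	False	does not transport bicarbonate
SLC9A1	SLC9	acid_extruder	False	localized to multiple subcellular compartments
SLC9A5	SLC9	acid_extruder	False	not expressed in any samples
SLC9A6	SLC9	acid_extruder	False	predominantly endosomal
SLC9A7	SLC9	acid_extruder	False	localized to multiple subcellular compartments
SLC9A8	SLC9	acid_extruder	False	localized only in Golgi
SLC26A3	SLC26	acid_loader	False	not expressed in majority of tissue types
SLC26A4	SLC26	acid_loader	False	not expressed in majority of tissue types
SLC26A7	SLC26	acid_loader	False	mainly a chloride channel, non-specific anion exchange
SLC26A11	SLC26	acid_loader	False	localized to five subcellular compartments
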