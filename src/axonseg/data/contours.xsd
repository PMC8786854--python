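<?xml version="1.0" encoding="UTF-8"?>
<!-- Contour export dialect: one <contour> per detected instance, holding the
     outer boundary polygon as whitespace-separated "row,col" pixel-corner
     coordinates (0-based, y-down). -->
<xs:schema xmlns:xs="http://www.w3.org/2001/XMLSchema">
  <xs:element name="contours">
    <xs:complexType>
      <xs:sequence>
        <xs:element name="contour" minOccurs="0" maxOccurs="unbounded">
          <xs:complexType>
            <xs:sequence>
              <xs:element name="points" type="xs:string"/>
            </xs:sequence>
            <xs:attribute name="id" type="xs:positiveInteger" use="required"/>
            <xs:attribute name="area" type="xs:double" use="required"/>
          </xs:complexType>
        </xs:element>
      </xs:sequence>
      <xs:attribute name="units" type="xs:string" use="required"/>
      <xs:attribute name="image" type="xs:string"/>
    </xs:complexType>
  </xs:element>
</xs:schema>
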